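"""The iterative fusion loop: diffuse cells, solve, classify, update, record.

Each weekly iteration (1 iteration = 7 days, 15 iterations ~ 105 days):

1. advance the cell field one week;
2. solve every load case on the current-property FE model;
3. combine the per-case stimuli by their daily duty fractions;
4. classify each callus element (resorb / bone / cartilage / fibrous);
5. update the tissue state (cell gating, ossification front, mixtures);
6. record metrics (bone volume %, biological stiffness, resorption zone,
   bridging).

Two loading protocols are provided: pure compression (500 N) and a hybrid
habitual-flexion protocol (63 % of the day compression + flexion, 37 %
pure compression).  The flexion moment is calibrated once, on the week-1
granulation-state model, such that the habitual flexion range of motion
matches the physiological target: the untreated segments of the lumbar
spine are represented by a lumped series flexibility, so the calibrated
moment is the load at which the whole (mostly intact) spine reaches the
physiological flexion ROM while the fused segment rotates only slightly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .construct import CALLUS, ConstructParams, LabeledMesh, build_construct
from .diffusion import (
    CallusDiffusion,
    DiffusionParams,
    calibrate_D,
    initial_field,
)
from .errors import CalibrationError, FusesimError, ParameterError
from .fem import (
    ConstrainedSystem,
    FESystem,
    LoadSpec,
    StimulusField,
    assemble_system,
    element_stimuli,
    load_vector,
    rom_flexion_angle,
)
from .materials import MaterialLibrary
from .metrics import (
    bone_volume_pct,
    bridging_detected,
    resorption_zone_pct,
    stiffness_without_implants,
)
from .regulation import (
    CallusTopology,
    RuleThresholds,
    classify,
    combine_load_cases,
    initial_tissue,
    update_state,
)

#: Physiological whole-lumbar-spine flexion ROM at 7.5 Nm + 500 N preload.
TARGET_ROM_DEG = 19.37
PHYSIOLOGICAL_MOMENT_NMM = 7500.0
#: Lumped flexion flexibility (deg per N*mm) of the three untreated motion
#: segments, assuming four equally flexible healthy segments share the
#: physiological ROM.  Used as a series compliance during moment calibration.
ADJACENT_FLEXIBILITY_DEG_PER_NMM = (TARGET_ROM_DEG * 3 / 4) / PHYSIOLOGICAL_MOMENT_NMM


@dataclass(frozen=True)
class ProtocolConfig:
    """A loading protocol: named set of daily load cases."""

    name: str
    load_cases: tuple[LoadSpec, ...]
    n_iterations: int = 15
    target_rom_deg: float = TARGET_ROM_DEG
    rom_tolerance_deg: float = 0.05
    adjacent_flexibility: float = ADJACENT_FLEXIBILITY_DEG_PER_NMM

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ParameterError("n_iterations must be >= 1")
        total = sum(c.duty_fraction for c in self.load_cases)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"duty fractions must sum to 1, got {total}")

    @property
    def needs_moment_calibration(self) -> bool:
        return any(c.flexion_moment is None for c in self.load_cases)

    def resolved(self, moment: float) -> "ProtocolConfig":
        cases = tuple(
            replace(c, flexion_moment=moment) if c.flexion_moment is None else c
            for c in self.load_cases
        )
        return replace(self, load_cases=cases)


def make_compression_protocol(force: float = 500.0, n_iterations: int = 15) -> ProtocolConfig:
    """Pure-compression protocol: one load case, full duty."""
    if not force > 0:
        raise ParameterError(f"compressive force must be > 0, got {force}")
    return ProtocolConfig(
        name="compression",
        load_cases=(LoadSpec(axial_force=force, flexion_moment=0.0, duty_fraction=1.0),),
        n_iterations=n_iterations,
    )


def make_hybrid_protocol(
    force: float = 500.0,
    flex_duty: float = 0.63,
    target_rom_deg: float = TARGET_ROM_DEG,
    n_iterations: int = 15,
    adjacent_flexibility: float = ADJACENT_FLEXIBILITY_DEG_PER_NMM,
) -> ProtocolConfig:
    """Habitual-flexion protocol: flexed (duty 0.63) + upright (duty 0.37).

    The flexion moment is left unresolved (None) and calibrated at run
    start against ``target_rom_deg``.
    """
    if not force > 0:
        raise ParameterError(f"compressive force must be > 0, got {force}")
    if not (0 < flex_duty < 1):
        raise ParameterError(f"flex_duty must be in (0, 1), got {flex_duty}")
    return ProtocolConfig(
        name="hybrid",
        load_cases=(
            LoadSpec(axial_force=force, flexion_moment=None, duty_fraction=flex_duty),
            LoadSpec(axial_force=force, flexion_moment=0.0, duty_fraction=1 - flex_duty),
        ),
        n_iterations=n_iterations,
        target_rom_deg=target_rom_deg,
        adjacent_flexibility=adjacent_flexibility,
    )


def calibrate_flexion_moment(
    system: FESystem | ConstrainedSystem,
    preload: float,
    target_rom_deg: float = TARGET_ROM_DEG,
    tol_deg: float = 0.05,
    adjacent_flexibility: float = ADJACENT_FLEXIBILITY_DEG_PER_NMM,
    moment_max: float = 1e6,
    probe_moment: float = 1e3,
    max_iter: int = 8,
) -> float:
    """Flexion moment (N*mm) at which the habitual-flexion ROM matches the
    physiological target.

    The total ROM is the construct's best-fit rigid flexion angle plus the
    lumped rotation of the untreated segments (adjacent_flexibility * M).
    Under linear elasticity theta(M) is affine, so a secant step from two
    solves lands on the target; the loop only repeats on roundoff.
    With adjacent_flexibility = 0 the target is the construct's own ROM.
    """
    cs = (
        system
        if isinstance(system, ConstrainedSystem)
        else system.factorize(system.mesh.node_sets["caudal_fixed"])
    )
    mesh = cs.system.mesh

    def theta(M: float) -> float:
        u = cs.solve(load_vector(mesh, LoadSpec(axial_force=preload, flexion_moment=M)))
        return rom_flexion_angle(mesh, u) + adjacent_flexibility * M

    th0 = theta(0.0)
    if abs(target_rom_deg - th0) <= tol_deg:
        return 0.0
    if target_rom_deg < th0:
        raise CalibrationError(
            f"target ROM {target_rom_deg} deg below preload-only ROM {th0:.3f} deg"
        )
    m_prev, th_prev = 0.0, th0
    m_cur, th_cur = probe_moment, theta(probe_moment)
    for _ in range(max_iter):
        slope = (th_cur - th_prev) / (m_cur - m_prev)
        if slope <= 0:
            raise CalibrationError("ROM does not increase with flexion moment")
        m_next = m_cur + (target_rom_deg - th_cur) / slope
        if not (0 <= m_next <= moment_max):
            raise CalibrationError(
                f"target ROM unreachable with moment <= {moment_max} N*mm"
            )
        th_next = theta(m_next)
        if abs(th_next - target_rom_deg) <= tol_deg:
            return float(m_next)
        m_prev, th_prev, m_cur, th_cur = m_cur, th_cur, m_next, th_next
    raise CalibrationError("flexion-moment calibration did not converge")


@dataclass
class SimHistory:
    """Weekly metric records plus the run manifest."""

    records: list[dict] = field(default_factory=list)
    calibrated_D: float = float("nan")
    calibrated_moment_Nmm: float = 0.0
    manifest: dict = field(default_factory=dict)

    def to_frame(self):
        from .io import history_frame

        return history_frame(self.records)


def _config_echo(**kwargs) -> dict:
    def enc(v):
        if hasattr(v, "__dict__"):
            return {k: enc(w) for k, w in vars(v).items()}
        if isinstance(v, (tuple, list)):
            return [enc(w) for w in v]
        return v

    return {k: enc(v) for k, v in kwargs.items()}


def run(
    construct: ConstructParams | LabeledMesh | None = None,
    materials: MaterialLibrary | None = None,
    rules: RuleThresholds | None = None,
    protocol: ProtocolConfig | None = None,
    diffusion: DiffusionParams | None = None,
    *,
    cage_material: str = "peek",
    front_rule: bool = True,
    n_min: float = 0.25,
    combine_mode: str = "weighted",
    material_window: int = 3,
    D: float | None = None,
    stiffness_probe_force: float = 500.0,
    compute_stiffness: bool = True,
    recalibrate_moment: bool = False,
    fields_dir=None,
    on_iteration=None,
    seed: int = 0,
) -> SimHistory:
    """Run the full iterative fusion simulation; returns the SimHistory.

    ``D=None`` triggers diffusion-coefficient calibration (coverage of the
    fusion region by week 4).  The initial state is all-granulation callus
    with cells only on the endplate source.  Deterministic for a fixed
    configuration.
    """
    materials = materials if materials is not None else MaterialLibrary()
    rules = rules if rules is not None else RuleThresholds()
    protocol = protocol if protocol is not None else make_compression_protocol()
    dbase = diffusion if diffusion is not None else DiffusionParams()

    mesh = construct if isinstance(construct, LabeledMesh) else build_construct(construct)
    topo = CallusTopology(mesh)
    diff_op = CallusDiffusion(mesh)
    if D is None:
        D = calibrate_D(
            mesh,
            threshold=dbase.coverage_threshold,
            dt=dbase.dt,
            operator=diff_op,
        )
    dparams = DiffusionParams(D=D, dt=dbase.dt, coverage_threshold=dbase.coverage_threshold)

    callus_idx = mesh.elements_of(CALLUS)
    E = np.empty(mesh.n_elements)
    nu = np.empty(mesh.n_elements)
    for region, (e, v) in materials.region_constants(cage_material).items():
        m = mesh.element_region == region
        E[m], nu[m] = e, v

    tissue = initial_tissue(mesh, materials)
    cells = initial_field(mesh)
    fixed = mesh.node_sets["caudal_fixed"]
    preload = max((c.axial_force for c in protocol.load_cases), default=0.0)
    moment: float | None = None

    history = SimHistory()
    prev_E = None
    cs = None
    try:
        for k in range(1, protocol.n_iterations + 1):
            cells = diff_op.step_week(cells, dparams)
            E[callus_idx] = tissue.effective_E
            nu[callus_idx] = tissue.effective_nu
            if prev_E is None or not np.array_equal(E, prev_E):
                system = assemble_system(mesh, E, nu)
                cs = system.factorize(fixed)
                prev_E = E.copy()

            if protocol.needs_moment_calibration and (moment is None or recalibrate_moment):
                moment = calibrate_flexion_moment(
                    cs,
                    preload=preload,
                    target_rom_deg=protocol.target_rom_deg,
                    tol_deg=protocol.rom_tolerance_deg,
                    adjacent_flexibility=protocol.adjacent_flexibility,
                )
            resolved = protocol.resolved(moment if moment is not None else 0.0)

            stim_callus = []
            last_u = None
            for case in resolved.load_cases:
                u = cs.solve(load_vector(mesh, case))
                last_u = u
                s = element_stimuli(mesh, u, E, nu)
                stim_callus.append(
                    StimulusField(
                        eps_min_pct=s.eps_min_pct[callus_idx],
                        p_hyd=s.p_hyd[callus_idx],
                    )
                )
            duties = [c.duty_fraction for c in resolved.load_cases]
            combined = combine_load_cases(stim_callus, duties, combine_mode)
            targets = classify(combined.eps_min_pct, combined.p_hyd, rules)
            resorb_pct = resorption_zone_pct(combined, rules, mesh)
            tissue = update_state(
                tissue, targets, cells, mesh,
                front_rule=front_rule, n_min=n_min,
                materials=materials, topology=topo,
                material_window=material_window,
            )
            record = {
                "iteration": k,
                "week": k,
                "bone_volume_pct": bone_volume_pct(tissue, mesh),
                "stiffness_N_per_mm": (
                    stiffness_without_implants(
                        mesh, tissue, stiffness_probe_force, materials
                    )
                    if compute_stiffness
                    else float("nan")
                ),
                "resorption_zone_pct": resorb_pct,
                "bridged": bridging_detected(tissue, mesh, topo),
            }
            history.records.append(record)
            if on_iteration is not None:
                on_iteration(k, tissue, combined, cells)

            if fields_dir is not None:
                _export_iteration(
                    mesh, fields_dir, k, tissue, cells, combined, callus_idx, E, last_u
                )
    except FusesimError as exc:
        exc.partial_history = history  # diagnostic: metrics up to the failure
        if fields_dir is not None:
            from .io import export_vtu

            export_vtu(mesh, f"{fields_dir}/diagnostic_failure.vtu",
                       cell_data={"E_eff": E}, point_data={"n": cells})
        raise

    history.calibrated_D = float(D)
    history.calibrated_moment_Nmm = float(moment) if moment is not None else 0.0
    import scipy

    config = _config_echo(
        rules=rules, protocol=protocol, diffusion=dparams,
        cage_material=cage_material, front_rule=front_rule, n_min=n_min,
        combine_mode=combine_mode, material_window=material_window, seed=seed,
    )
    if not isinstance(construct, LabeledMesh):
        config["construct"] = _config_echo(
            params=construct if construct is not None else ConstructParams()
        )["params"]
    blob = json.dumps(config, sort_keys=True, default=str)
    history.manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "calibrated_D_mm2_per_day": history.calibrated_D,
        "calibrated_moment_Nmm": history.calibrated_moment_Nmm,
        "seed": seed,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
    }
    return history


def _export_iteration(mesh, fields_dir, k, tissue, cells, combined, callus_idx, E, u):
    from .io import export_vtu

    phen = np.full(mesh.n_elements, -1, dtype=np.int64)
    phen[callus_idx] = tissue.phenotype
    eps = np.zeros(mesh.n_elements)
    p = np.zeros(mesh.n_elements)
    eps[callus_idx] = combined.eps_min_pct
    p[callus_idx] = combined.p_hyd
    point_data = {"n": cells}
    if u is not None:
        point_data["displacement"] = u
    export_vtu(
        mesh,
        f"{fields_dir}/fields_{k:03d}.vtu",
        cell_data={"phenotype": phen, "E_eff": E.copy(),
                   "eps_min_pct": eps, "p_hyd": p},
        point_data=point_data,
    )
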