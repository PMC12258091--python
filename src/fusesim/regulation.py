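"""Tissue differentiation rules: mechanical stimuli -> phenotype updates.

The rule engine maps each callus element's (minimum-principal-strain
magnitude in %, hydrostatic pressure in MPa) to a target outcome:

* RESORB      if eps < eps_resorb AND |p| < p_resorb   (mechanically idle)
* BONE        if eps <= eps_bone AND |p| <= p_bone     (and not RESORB)
* CARTILAGE   if p > p_bone AND eps <= eps_cart
* FIBROUS     otherwise

The resorption limits (0.1 %, 0.15 MPa) follow the lumbar-fusion healing
literature; the bone/cartilage/fibrous boundaries follow the Claes-Heigele
rule family and are configurable.

Differentiation is gated by cell availability (element-mean density
n_bar >= n_min) and, optionally, by an ossification front: bone may only
form in elements face-adjacent to existing bone or to the vertebral bone
interface.  Element stiffness follows a rule of mixtures between
granulation tissue and the phenotype's modulus, weighted by n_bar.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import scipy.sparse as sp

from .construct import (
    BONE_REGIONS,
    CALLUS,
    LabeledMesh,
    face_adjacency,
    interface_elements,
)
from .errors import ParameterError
from .fem import StimulusField
from .materials import MaterialLibrary


class Phenotype(IntEnum):
    GRANULATION = 0
    FIBROUS = 1
    CARTILAGE = 2
    BONE = 3


RESORB = -1  # classification signal, not a phenotype

PHENOTYPE_MATERIAL = {
    Phenotype.GRANULATION: "granulation",
    Phenotype.FIBROUS: "fibrous",
    Phenotype.CARTILAGE: "cartilage",
    Phenotype.BONE: "bone",
}


@dataclass(frozen=True)
class RuleThresholds:
    """Decision-band boundaries of the differentiation rules."""

    eps_resorb_pct: float = 0.1   # below this (and p_resorb): resorption
    p_resorb: float = 0.15        # MPa
    eps_bone_pct: float = 5.0
    p_bone: float = 0.15          # MPa
    eps_cart_pct: float = 15.0

    def __post_init__(self):
        if not (0 < self.eps_resorb_pct < self.eps_bone_pct < self.eps_cart_pct):
            raise ParameterError(
                "need 0 < eps_resorb_pct < eps_bone_pct < eps_cart_pct"
            )
        if not (0 < self.p_resorb <= self.p_bone):
            raise ParameterError("need 0 < p_resorb <= p_bone")


def classify(
    eps_min_pct: np.ndarray | float,
    p_hyd: np.ndarray | float,
    rules: RuleThresholds = RuleThresholds(),
) -> np.ndarray | int:
    """Target outcome per element: RESORB or a Phenotype value.

    Total on the finite (eps, p) plane; band boundaries: resorption bounds
    open (strict <), bone bounds closed (<=), cartilage requires p strictly
    above p_bone.
    """
    scalar = np.isscalar(eps_min_pct) and np.isscalar(p_hyd)
    eps = np.atleast_1d(np.asarray(eps_min_pct, dtype=float))
    p = np.atleast_1d(np.asarray(p_hyd, dtype=float))
    if not (np.all(np.isfinite(eps)) and np.all(np.isfinite(p))):
        raise ParameterError("non-finite stimulus passed to classify")
    out = np.full(eps.shape, int(Phenotype.FIBROUS), dtype=np.int64)
    resorb = (eps < rules.eps_resorb_pct) & (np.abs(p) < rules.p_resorb)
    bone = ~resorb & (eps <= rules.eps_bone_pct) & (np.abs(p) <= rules.p_bone)
    cart = ~resorb & ~bone & (p > rules.p_bone) & (eps <= rules.eps_cart_pct)
    out[cart] = int(Phenotype.CARTILAGE)
    out[bone] = int(Phenotype.BONE)
    out[resorb] = RESORB
    return int(out[0]) if scalar else out


def combine_load_cases(
    stimuli: list[StimulusField],
    duties: list[float],
    mode: str = "weighted",
) -> StimulusField:
    """Combine per-load-case stimuli into one daily stimulus field.

    "weighted": duty-weighted mean of eps and p (time-averaged exposure).
    "max": per element, the stimuli of the case with the larger eps.
    """
    if len(stimuli) != len(duties) or not stimuli:
        raise ParameterError("need one duty fraction per stimulus field")
    if abs(sum(duties) - 1.0) > 1e-9:
        raise ParameterError(f"duty fractions must sum to 1, got {sum(duties)}")
    n = stimuli[0].eps_min_pct.shape[0]
    for s in stimuli:
        if s.eps_min_pct.shape[0] != n:
            raise ParameterError("stimulus fields live on different meshes")
    eps = np.stack([s.eps_min_pct for s in stimuli])
    p = np.stack([s.p_hyd for s in stimuli])
    w = np.asarray(duties, dtype=float)[:, None]
    if mode == "weighted":
        return StimulusField(eps_min_pct=(w * eps).sum(0), p_hyd=(w * p).sum(0))
    if mode == "max":
        pick = np.argmax(eps, axis=0)
        cols = np.arange(n)
        return StimulusField(eps_min_pct=eps[pick, cols], p_hyd=p[pick, cols])
    raise ParameterError(f"unknown combine mode {mode!r}")


@dataclass
class TissueState:
    """Per-callus-element phenotype and effective material properties."""

    phenotype: np.ndarray                # (nc,) Phenotype values
    effective_E: np.ndarray              # (nc,) MPa
    effective_nu: np.ndarray             # (nc,)
    iterations_in_phenotype: np.ndarray  # (nc,) int
    # rolling log of rule-of-mixtures target moduli, most recent row last;
    # only kept when a material-update window > 1 is used
    E_target_log: np.ndarray | None = None

    def copy(self) -> "TissueState":
        return TissueState(
            self.phenotype.copy(),
            self.effective_E.copy(),
            self.effective_nu.copy(),
            self.iterations_in_phenotype.copy(),
            None if self.E_target_log is None else self.E_target_log.copy(),
        )


def initial_tissue(mesh: LabeledMesh, materials: MaterialLibrary) -> TissueState:
    """All-granulation state: the early post-surgical fusion region."""
    nc = mesh.elements_of(CALLUS).size
    E, nu = materials.table["granulation"]
    return TissueState(
        phenotype=np.full(nc, int(Phenotype.GRANULATION), dtype=np.int64),
        effective_E=np.full(nc, E),
        effective_nu=np.full(nc, nu),
        iterations_in_phenotype=np.ones(nc, dtype=np.int64),
    )


class CallusTopology:
    """Face-adjacency of the callus elements and their bone interfaces."""

    def __init__(self, mesh: LabeledMesh):
        self.mesh = mesh
        self.callus_elements = mesh.elements_of(CALLUS)
        nc = self.callus_elements.size
        pairs = face_adjacency(mesh, self.callus_elements)
        if pairs.size:
            i = np.concatenate([pairs[:, 0], pairs[:, 1]])
            j = np.concatenate([pairs[:, 1], pairs[:, 0]])
            self.adjacency = sp.coo_matrix(
                (np.ones(i.size, dtype=bool), (i, j)), shape=(nc, nc)
            ).tocsr()
        else:
            self.adjacency = sp.csr_matrix((nc, nc), dtype=bool)

        iface = interface_elements(mesh, CALLUS, BONE_REGIONS)
        self.touches_bone = np.zeros(nc, dtype=bool)
        self.touches_cranial = np.zeros(nc, dtype=bool)
        self.touches_caudal = np.zeros(nc, dtype=bool)
        if iface.size:
            self.touches_bone[iface[:, 0]] = True
            self.touches_cranial[iface[iface[:, 1] > 0, 0]] = True
            self.touches_caudal[iface[iface[:, 1] < 0, 0]] = True

    def adjacent_to(self, mask: np.ndarray) -> np.ndarray:
        """Elements face-adjacent to any element in the boolean mask."""
        return (self.adjacency @ mask).astype(bool)


def element_mean_density(mesh: LabeledMesh, cells: np.ndarray) -> np.ndarray:
    """Element-mean normalized cell density n_bar over callus elements."""
    return cells[mesh.tets[mesh.elements_of(CALLUS)]].mean(axis=1)


def update_state(
    tissue: TissueState,
    targets: np.ndarray,
    cells: np.ndarray,
    mesh: LabeledMesh,
    front_rule: bool = True,
    n_min: float = 0.25,
    materials: MaterialLibrary | None = None,
    topology: CallusTopology | None = None,
    material_window: int = 1,
) -> TissueState:
    """Apply one iteration of tissue differentiation.

    Resorption reverts an element to granulation; differentiation requires
    element-mean cell density >= n_min; with the front rule on, bone forms
    only face-adjacent to existing bone or to the vertebral interface.
    The rule-of-mixtures target stiffness is
    E_target = n_bar * E_phenotype + (1 - n_bar) * E_granulation.

    With ``material_window`` w > 1, the element modulus applied to the FE
    model is the mean of the last w weekly targets (granulation-padded at
    the start), so maturation and resorption change the stiffness
    gradually over ~w weeks.  This damps the form/resorb limit cycle of
    instantaneous property switching and reproduces the slow resorption
    of previously formed bone in stress-shielded zones; w = 1 recovers
    the undamped single-iteration update.
    """
    mat = materials if materials is not None else MaterialLibrary()
    topo = topology if topology is not None else CallusTopology(mesh)
    nbar = element_mean_density(mesh, cells)
    if targets.shape != tissue.phenotype.shape:
        raise ParameterError("targets and tissue state have mismatched sizes")

    is_bone = tissue.phenotype == int(Phenotype.BONE)
    is_cart = tissue.phenotype == int(Phenotype.CARTILAGE)
    may_differentiate = nbar >= n_min

    new_phen = tissue.phenotype.copy()
    new_phen[targets == RESORB] = int(Phenotype.GRANULATION)

    new_phen[(targets == int(Phenotype.FIBROUS)) & may_differentiate] = int(
        Phenotype.FIBROUS
    )
    # CARTILAGE band = endochondral ossification route: soft tissue becomes
    # cartilage; existing bone persists (it is load-bearing, which is what
    # raised its hydrostatic pressure); existing cartilage ossifies below
    cart_target = (targets == int(Phenotype.CARTILAGE)) & may_differentiate
    new_phen[cart_target & ~is_bone] = int(Phenotype.CARTILAGE)

    # bone formation: intramembranous (BONE band) on any tissue, or
    # endochondral (CARTILAGE band) maturation of existing cartilage
    bone_target = (targets == int(Phenotype.BONE)) | (
        (targets == int(Phenotype.CARTILAGE)) & is_cart
    )
    bone_target &= may_differentiate
    if front_rule:
        # resorption/overload is applied before the adjacency check: new
        # bone may only attach to bone that survives this iteration, or to
        # the vertebral interface (no orphaned bone behind a resorbing
        # front layer)
        surviving_bone = is_bone & (targets != RESORB) & (
            targets != int(Phenotype.FIBROUS)
        )
        front_ok = topo.touches_bone | topo.adjacent_to(surviving_bone) | surviving_bone
        bone_target &= front_ok
    new_phen[bone_target] = int(Phenotype.BONE)

    if front_rule:
        # closure of the front rule: bone must stay face-connected to the
        # vertebral interface; islands isolated by resorption of their
        # connecting elements revert to granulation
        from scipy.sparse.csgraph import connected_components

        bone_now = new_phen == int(Phenotype.BONE)
        if bone_now.any():
            sub = topo.adjacency[bone_now][:, bone_now]
            _, labels = connected_components(sub, directed=False)
            seeded = np.unique(labels[topo.touches_bone[bone_now]])
            orphan = ~np.isin(labels, seeded)
            idx = np.flatnonzero(bone_now)[orphan]
            new_phen[idx] = int(Phenotype.GRANULATION)

    E_gran = mat.E("granulation")
    E_table = np.array([mat.E(PHENOTYPE_MATERIAL[Phenotype(i)]) for i in range(4)])
    nu_table = np.array([mat.nu(PHENOTYPE_MATERIAL[Phenotype(i)]) for i in range(4)])
    target_E = nbar * E_table[new_phen] + (1.0 - nbar) * E_gran
    eff_nu = nu_table[new_phen]

    if material_window <= 1:
        eff_E = target_E
        log = None
    else:
        prev = tissue.E_target_log
        if prev is None:
            prev = np.full((material_window - 1, target_E.size), E_gran)
        log = np.vstack([prev, target_E])[-material_window:]
        eff_E = log.mean(axis=0)

    changed = new_phen != tissue.phenotype
    iters = np.where(changed, 1, tissue.iterations_in_phenotype + 1)
    return TissueState(new_phen, eff_E, eff_nu, iters, log)
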