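"""Output quantities of a fusion simulation.

Bone volume fraction and the resorption-zone volume are normalized by the
CALLUS (intervertebral) volume only; the solid cages are excluded from
both numerator and denominator since they cannot ossify.  Bridging is a
face-connected path of bone elements joining the cranial and caudal
vertebral interfaces — the model's definition of arthrodesis.  Construct
stiffness "without the implants" softens cages and fixation to a
negligible modulus so the remaining bone/callus load path is probed.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import connected_components

from .construct import CALLUS, IMPLANT_REGIONS, LabeledMesh
from .errors import GeometryError
from .fem import LoadSpec, StimulusField, assemble_system, solve_static
from .materials import MaterialLibrary
from .regulation import (
    CallusTopology,
    Phenotype,
    RESORB,
    RuleThresholds,
    TissueState,
    classify,
)

IMPLANT_SOFT_E = 1e-3  # MPa, numerically negligible stand-in for removal


def _callus_volumes(mesh: LabeledMesh) -> np.ndarray:
    elems = mesh.elements_of(CALLUS)
    if elems.size == 0:
        raise GeometryError("mesh has no CALLUS elements")
    return mesh.element_volumes[elems]


def bone_volume_pct(tissue: TissueState, mesh: LabeledMesh) -> float:
    """Volume % of the intervertebral (callus) space occupied by bone."""
    vols = _callus_volumes(mesh)
    bone = tissue.phenotype == int(Phenotype.BONE)
    return 100.0 * float(vols[bone].sum() / vols.sum())


def bone_volume_weighted(
    tissue: TissueState, mesh: LabeledMesh, materials: MaterialLibrary | None = None
) -> float:
    """Stiffness-weighted bone volume %: each bone element counts by its
    maturity (E_eff - E_gran)/(E_bone - E_gran)."""
    mat = materials if materials is not None else MaterialLibrary()
    vols = _callus_volumes(mesh)
    bone = tissue.phenotype == int(Phenotype.BONE)
    e0, e1 = mat.E("granulation"), mat.E("bone")
    w = np.clip((tissue.effective_E - e0) / (e1 - e0), 0.0, 1.0)
    return 100.0 * float((vols * w * bone).sum() / vols.sum())


def bridging_detected(
    tissue: TissueState,
    mesh: LabeledMesh,
    topology: CallusTopology | None = None,
) -> bool:
    """True iff bone elements form a face-connected path between the
    cranial and caudal vertebral interfaces."""
    topo = topology if topology is not None else CallusTopology(mesh)
    bone = tissue.phenotype == int(Phenotype.BONE)
    if not (np.any(bone & topo.touches_cranial) and np.any(bone & topo.touches_caudal)):
        return False
    sub = topo.adjacency[bone][:, bone]
    _, labels = connected_components(sub, directed=False)
    cran = labels[topo.touches_cranial[bone]]
    caud = labels[topo.touches_caudal[bone]]
    return bool(np.intersect1d(cran, caud).size > 0)


def stiffness_without_implants(
    mesh: LabeledMesh,
    tissue: TissueState,
    force: float = 500.0,
    materials: MaterialLibrary | None = None,
) -> float:
    """Axial construct stiffness (N/mm) with cages and fixation softened
    to a negligible modulus, probing the biological load path."""
    mat = materials if materials is not None else MaterialLibrary()
    E = np.empty(mesh.n_elements)
    nu = np.empty(mesh.n_elements)
    for region, (e, v) in mat.region_constants().items():
        m = mesh.element_region == region
        E[m], nu[m] = e, v
    for region in IMPLANT_REGIONS:
        E[mesh.element_region == region] = IMPLANT_SOFT_E
    callus = mesh.elements_of(CALLUS)
    E[callus] = tissue.effective_E
    nu[callus] = tissue.effective_nu

    system = assemble_system(mesh, E, nu)
    u = solve_static(system, mesh.node_sets["caudal_fixed"], LoadSpec(axial_force=force))
    uz = u[mesh.node_sets["cranial_load"], 2].mean()
    return float(force / abs(uz))


def resorption_zone_pct(
    stimulus: StimulusField,
    rules: RuleThresholds,
    mesh: LabeledMesh,
) -> float:
    """Volume % of the callus under a resorption mechanical stimulus."""
    vols = _callus_volumes(mesh)
    callus = mesh.elements_of(CALLUS)
    targets = classify(stimulus.eps_min_pct[: len(callus)], stimulus.p_hyd[: len(callus)], rules) \
        if stimulus.eps_min_pct.shape[0] == len(callus) else None
    if targets is None:
        targets = classify(
            stimulus.eps_min_pct[callus], stimulus.p_hyd[callus], rules
        )
    resorb = targets == RESORB
    return 100.0 * float(vols[resorb].sum() / vols.sum())
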