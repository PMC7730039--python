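"""Histomorphometric scoring of the healing chamber region.

Bone-implant contact (BIC) is the percentage of the thread interface length
(upper/lower flanks and roots; crest lands excluded) whose adjacent callus
element is mature or immature bone.  Bone area (BA) is the percentage of
the inter-thread chamber area occupied by bone elements.  Areas and the
modulus averages use in-plane element areas by default, mimicking a 2D
histology section; a volume-weighting switch (2*pi*r) is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ROI",
    "MorphometryResult",
    "extract_roi",
    "bone_implant_contact",
    "bone_area",
    "mean_modulus_history",
    "modulus_histogram",
    "morphometry_result",
]

BONE_PHENOTYPES = ("mature_bone", "immature_bone")

#: profile segment kinds that belong to the BIC interface ROI
_ROI_KINDS = {"flank_upper", "flank_lower", "root"}


@dataclass
class ROI:
    """Thread-interface edges and inter-thread chamber elements."""

    interface_edges: np.ndarray  # (K, 2) node pairs on flanks/roots
    edge_lengths: np.ndarray  # (K,) mm
    area_elements: np.ndarray  # element ids inside the chambers
    element_areas: np.ndarray  # (len(area_elements),) mm^2 in-plane


def extract_roi(mesh, profile) -> ROI:
    """Identify the BIC edge set and the BA chamber element set.

    Edges are classified by the profile segment their midpoint lies on;
    crest and collar faces and the tip are excluded.  Chamber elements are
    callus elements whose centroid falls radially between the local profile
    radius and the thread crest within a chamber's axial span.
    """
    if "implant_callus_interface" not in mesh.edge_sets:
        raise ValueError("mesh lacks the implant_callus_interface edge set")
    edges = mesh.edge_sets["implant_callus_interface"]
    keep, lengths = [], []
    for a, b in edges:
        xa, xb = mesh.node_coords[int(a)], mesh.node_coords[int(b)]
        mid_y = 0.5 * (xa[1] + xb[1])
        if profile.segment_kind(mid_y) in _ROI_KINDS and mid_y > profile.y_tip:
            keep.append((int(a), int(b)))
            lengths.append(float(np.linalg.norm(xb - xa)))
    keep_arr = np.array(keep, dtype=int).reshape(-1, 2)

    cal_ids = mesh.elements_in_region("callus")
    cent = mesh.element_centroids()[cal_ids]
    R = profile.core_radius
    in_roi = np.zeros(len(cal_ids), dtype=bool)
    for y_lo, y_hi in profile.chamber_spans:
        span = (cent[:, 1] > y_lo) & (cent[:, 1] < y_hi) & (cent[:, 0] < R)
        in_roi |= span
    area_ids = cal_ids[in_roi]
    return ROI(keep_arr, np.array(lengths), area_ids,
               mesh.element_areas()[area_ids])


def _edge_adjacency(mesh) -> dict[tuple[int, int], list[int]]:
    adj: dict[tuple[int, int], list[int]] = {}
    for e, conn in enumerate(mesh.elements):
        for i in range(4):
            a, b = int(conn[i]), int(conn[(i + 1) % 4])
            adj.setdefault((min(a, b), max(a, b)), []).append(e)
    return adj


def _adjacent_callus_elements(mesh, roi: ROI) -> np.ndarray:
    adj = _edge_adjacency(mesh)
    out = np.empty(len(roi.interface_edges), dtype=int)
    for i, (a, b) in enumerate(roi.interface_edges):
        cands = [e for e in adj[(min(a, b), max(a, b))]
                 if mesh.element_region[e] == "callus"]
        if not cands:
            raise ValueError(f"ROI edge ({a}, {b}) has no adjacent callus element")
        out[i] = cands[0]
    return out


def bone_implant_contact(phenotypes: np.ndarray, roi: ROI, mesh,
                         by_phenotype: bool = False):
    """BIC percent: bone-adjacent fraction of the ROI interface length."""
    if len(roi.interface_edges) == 0:
        return ({}, 0.0) if by_phenotype else 0.0
    elems = _adjacent_callus_elements(mesh, roi)
    phen = np.asarray(phenotypes)[elems]
    total = roi.edge_lengths.sum()
    split = {ph: 100.0 * roi.edge_lengths[phen == ph].sum() / total
             for ph in BONE_PHENOTYPES}
    bic = sum(split.values())
    return (split, bic) if by_phenotype else bic


def bone_area(phenotypes: np.ndarray, roi: ROI, mesh,
              by_phenotype: bool = False, weighting: str = "area"):
    """BA percent: bone fraction of the inter-thread chamber area."""
    if len(roi.area_elements) == 0:
        return ({}, 0.0) if by_phenotype else 0.0
    w = roi.element_areas.copy()
    if weighting == "volume":
        w = w * 2 * np.pi * mesh.element_centroids()[roi.area_elements, 0]
    elif weighting != "area":
        raise ValueError("weighting must be 'area' or 'volume'")
    phen = np.asarray(phenotypes)[roi.area_elements]
    total = w.sum()
    split = {ph: 100.0 * w[phen == ph].sum() / total for ph in BONE_PHENOTYPES}
    ba = sum(split.values())
    return (split, ba) if by_phenotype else ba


@dataclass
class MorphometryResult:
    bic_percent: float
    ba_percent: float
    bic_by_phenotype: dict[str, float]
    ba_by_phenotype: dict[str, float]
    mean_modulus: float  # MPa, callus average
    modulus_histogram: np.ndarray  # counts
    histogram_edges: np.ndarray  # MPa


DEFAULT_HISTOGRAM_EDGES = np.arange(0.0, 6500.0, 500.0)


def morphometry_result(phenotypes: np.ndarray, roi: ROI, mesh,
                       young: np.ndarray,
                       histogram_edges: np.ndarray = DEFAULT_HISTOGRAM_EDGES,
                       ) -> MorphometryResult:
    """Bundle BIC/BA (with phenotype splits), mean modulus and histogram."""
    bic_split, bic = bone_implant_contact(phenotypes, roi, mesh,
                                          by_phenotype=True)
    ba_split, ba = bone_area(phenotypes, roi, mesh, by_phenotype=True)
    cal = mesh.elements_in_region("callus")
    areas = mesh.element_areas()[cal]
    mean_mod = float(np.average(np.asarray(young)[cal], weights=areas))
    counts, edges = np.histogram(np.asarray(young)[cal], bins=histogram_edges)
    return MorphometryResult(bic, ba, bic_split, ba_split, mean_mod,
                             counts, edges)


def mean_modulus_history(history) -> np.ndarray:
    """Area-weighted callus mean Young's modulus per healing day, MPa."""
    return history.mean_modulus_series()


def modulus_histogram(young: np.ndarray, element_ids: np.ndarray,
                      bin_edges) -> np.ndarray:
    """Counts of callus elements per Young's-modulus bin."""
    counts, _ = np.histogram(np.asarray(young)[element_ids],
                             bins=np.asarray(bin_edges, dtype=float))
    return counts
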