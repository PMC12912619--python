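"""Individual-specific deposition networks via the perturbation Z-score.

The group reference network ``REN_n`` is the ROI x ROI Pearson correlation
of regional SUVRs across the n control subjects.  Adding one test subject
and recomputing yields the perturbed network ``CDN_{n+1}``; the subject's
individual network is the edge-wise Z-score of the perturbation

    delta = CDN_{n+1} - REN_n
    z     = delta / ((1 - CDN_{n+1}^2) / (n - 1))

where n is the reference group size.  Under the null (a subject drawn from
the reference distribution) delta follows a sharply peaked symmetric
distribution around zero, so z behaves like a standardized edge
perturbation; an edge whose underlying correlation differs in the subject's
population shifts z systematically.

For graph analysis each individual Z network is binarized over a grid of
sparsity thresholds, keeping only the strongest positive edges: at sparsity
s, the top floor(s * M) positive-weight edges of the M = R(R-1)/2 possible
edges are set to 1.  The resulting edge sets are nested along the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .suvr import SuvrMatrix

__all__ = [
    "ReferenceNetwork", "PerturbedNetwork", "IndividualNetwork",
    "BinaryGraphEnsemble", "build_reference_network",
    "build_perturbed_network", "perturbation_zscore", "fisher_transform",
    "binarize_ensemble", "individual_network", "individual_networks",
    "nodal_strength_table", "default_sparsity_grid",
]

_SATURATION = 1.0 - 1e-12


def default_sparsity_grid(s_min: float = 0.05, s_max: float = 0.35,
                          step: float = 0.01) -> np.ndarray:
    """The published grid: 0.05 to 0.35 in steps of 0.01 (31 thresholds)."""
    n = int(round((s_max - s_min) / step)) + 1
    grid = s_min + step * np.arange(n)
    return np.round(grid, 10)


def _check_square(matrix: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    r = len(names)
    if matrix.shape != (r, r):
        raise ValueError(f"matrix must be {r}x{r} to match ROI names")
    return matrix


@dataclass
class ReferenceNetwork:
    """Group-level correlation network over the reference (control) cohort."""

    roi_names: tuple[str, ...]
    matrix: np.ndarray
    n_reference: int

    def __post_init__(self) -> None:
        self.matrix = _check_square(self.matrix, self.roi_names)
        if self.n_reference < 3:
            raise ValueError("reference network needs >= 3 subjects")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("reference matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 1.0, atol=1e-10):
            raise ValueError("reference matrix must have unit diagonal")
        if np.abs(self.matrix).max() > 1 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.roi_names),
                            columns=list(self.roi_names))


@dataclass
class PerturbedNetwork:
    """Correlation network over the n reference subjects plus one added."""

    roi_names: tuple[str, ...]
    matrix: np.ndarray
    added_subject_id: str

    def __post_init__(self) -> None:
        self.matrix = _check_square(self.matrix, self.roi_names)


@dataclass
class IndividualNetwork:
    """Edge-wise perturbation Z network of one subject."""

    subject_id: str
    roi_names: tuple[str, ...]
    delta: np.ndarray
    z_matrix: np.ndarray
    n_reference: int
    fisher_applied: bool = False
    saturated_edges: list[tuple[int, int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z_matrix, index=list(self.roi_names),
                            columns=list(self.roi_names))

    def to_edge_list(self) -> pd.DataFrame:
        names = list(self.roi_names)
        rows = [(names[i], names[j], self.z_matrix[i, j])
                for i in range(len(names)) for j in range(i + 1, len(names))]
        return pd.DataFrame(rows, columns=["roi_i", "roi_j", "weight"])


@dataclass
class BinaryGraphEnsemble:
    """Stack of binarized adjacency matrices across the sparsity grid."""

    subject_id: str
    roi_names: tuple[str, ...]
    sparsity_grid: np.ndarray
    adjacency_stack: np.ndarray        # (n_thresholds, R, R), 0/1

    def __post_init__(self) -> None:
        t, r, r2 = self.adjacency_stack.shape
        if r != r2 or r != len(self.roi_names):
            raise ValueError("adjacency stack shape mismatch")
        if t != len(self.sparsity_grid):
            raise ValueError("one adjacency per sparsity threshold required")

    def edge_counts(self) -> np.ndarray:
        return self.adjacency_stack.sum(axis=(1, 2)) // 2

    def check_nesting(self) -> bool:
        """Edges at a smaller sparsity must be a subset of those at a
        larger one."""
        for k in range(len(self.sparsity_grid) - 1):
            a, b = self.adjacency_stack[k], self.adjacency_stack[k + 1]
            if np.any(a > b):
                return False
        return True


def _correlation(values: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
    sd = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        raise ValueError(
            f"zero-variance ROI(s): {[names[k] for k in zero]}")
    corr = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return np.clip((corr + corr.T) / 2, -1.0, 1.0)


def build_reference_network(suvr_cn: SuvrMatrix) -> ReferenceNetwork:
    """Pearson correlation of each ROI pair across the control subjects."""
    values = suvr_cn.values.to_numpy(dtype=float)
    if values.shape[0] < 3:
        raise ValueError("need >= 3 control subjects")
    names = tuple(suvr_cn.values.columns)
    return ReferenceNetwork(names, _correlation(values, names),
                            n_reference=values.shape[0])


def build_perturbed_network(suvr_cn: SuvrMatrix,
                            subject_row: pd.Series | np.ndarray,
                            subject_id: str = "") -> PerturbedNetwork:
    """Correlation network over the controls plus one appended subject."""
    names = tuple(suvr_cn.values.columns)
    if isinstance(subject_row, pd.Series):
        subject_id = subject_id or str(subject_row.name)
        subject_row = subject_row.reindex(list(names))
        if subject_row.isna().any():
            raise ValueError("subject row does not cover the template ROIs")
        subject_row = subject_row.to_numpy(dtype=float)
    subject_row = np.asarray(subject_row, dtype=float)
    if subject_row.shape != (len(names),):
        raise ValueError(
            f"subject row has {subject_row.shape} values, expected "
            f"{len(names)}")
    stacked = np.vstack([suvr_cn.values.to_numpy(dtype=float), subject_row])
    return PerturbedNetwork(names, _correlation(stacked, names),
                            added_subject_id=subject_id)


def perturbation_zscore(ren: ReferenceNetwork,
                        cdn: PerturbedNetwork,
                        use_sqrt_denominator: bool = False) -> IndividualNetwork:
    """Edge-wise Z of the perturbation delta = CDN - REN.

    The denominator is (1 - CDN^2) / (n - 1) as printed in the individual-
    network method; ``use_sqrt_denominator=True`` switches to the
    standard-error variant sqrt((1 - CDN^2) / (n - 1)) for sensitivity
    analysis.  Off-diagonal |CDN| at 1 is clipped to 1 - 1e-12 with a
    warning so outputs stay finite (saturation rule).
    """
    if ren.roi_names != cdn.roi_names:
        raise ValueError("reference and perturbed networks have different "
                         "ROI names")
    n = ren.n_reference
    delta = cdn.matrix - ren.matrix
    c = cdn.matrix.copy()
    off = ~np.eye(len(ren.roi_names), dtype=bool)
    sat = off & (np.abs(c) >= _SATURATION)
    saturated: list[tuple[int, int]] = []
    if sat.any():
        idx = np.argwhere(sat)
        saturated = [tuple(p) for p in idx[idx[:, 0] < idx[:, 1]]]
        warnings.warn(f"{len(saturated)} edge(s) with |correlation| ~ 1 "
                      "clipped before the Z denominator", RuntimeWarning)
        c[sat] = np.sign(c[sat]) * _SATURATION
    denom = (1.0 - c ** 2) / (n - 1)
    if use_sqrt_denominator:
        denom = np.sqrt(denom)
    np.fill_diagonal(denom, 1.0)      # diagonal delta is 0; avoid 0/0
    z = delta / denom
    np.fill_diagonal(z, 0.0)
    np.fill_diagonal(delta, 0.0)
    z = (z + z.T) / 2
    delta = (delta + delta.T) / 2
    return IndividualNetwork(subject_id=cdn.added_subject_id,
                             roi_names=ren.roi_names, delta=delta,
                             z_matrix=z, n_reference=n,
                             saturated_edges=saturated)


def fisher_transform(matrix: np.ndarray, epsilon: float = 1e-7) -> np.ndarray:
    """Entry-wise arctanh of a correlation-valued matrix.

    Defined only on correlation scales: any off-diagonal entry outside
    [-1, 1] raises (a Z-scored matrix is not a valid input).  Entries at
    exactly +/-1 are clipped by *epsilon* with a warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    off = ~np.eye(matrix.shape[0], dtype=bool)
    if np.abs(matrix[off]).max(initial=0.0) > 1.0:
        raise ValueError("Fisher transform requires entries in [-1, 1]; "
                         "input does not look correlation-valued")
    clipped = np.clip(matrix, -1.0 + epsilon, 1.0 - epsilon)
    if np.any(np.abs(matrix[off]) >= 1.0):
        warnings.warn("correlation(s) at +/-1 clipped before arctanh",
                      RuntimeWarning)
    out = np.arctanh(clipped)
    np.fill_diagonal(out, 0.0)
    return (out + out.T) / 2


def binarize_ensemble(weights: IndividualNetwork | np.ndarray,
                      grid: np.ndarray | None = None,
                      subject_id: str = "",
                      roi_names: tuple[str, ...] | None = None,
                      ) -> BinaryGraphEnsemble:
    """Binarize a weighted network over the sparsity grid.

    Only positive weights are considered; at each sparsity s, the strongest
    floor(s * M) of them are kept (fewer if fewer positive weights exist).
    Ties are broken by (row, column) lexicographic order, so the output is
    platform-independent.  The edge sets are nested along the grid by
    construction.
    """
    if isinstance(weights, IndividualNetwork):
        subject_id = subject_id or weights.subject_id
        roi_names = roi_names or weights.roi_names
        w = weights.z_matrix
    else:
        w = np.asarray(weights, dtype=float)
        roi_names = roi_names or tuple(f"roi{k}" for k in range(w.shape[0]))
    grid = default_sparsity_grid() if grid is None else np.asarray(grid, float)
    if len(grid) == 0 or np.any(grid <= 0) or np.any(grid > 1):
        raise ValueError("sparsity grid values must lie in (0, 1]")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sparsity grid must be strictly increasing")

    r = w.shape[0]
    iu, ju = np.triu_indices(r, k=1)
    vals = w[iu, ju]
    m = len(vals)                     # M = R(R-1)/2 possible edges
    pos = vals > 0
    if not pos.any():
        warnings.warn(f"subject {subject_id!r}: no positive weights; "
                      "all binary graphs are empty", RuntimeWarning)
    # sort positive edges by decreasing weight, ties by (row, col) index
    order = np.lexsort((ju, iu, -vals))
    order = order[pos[order]]
    stack = np.zeros((len(grid), r, r), dtype=np.int8)
    for k, s in enumerate(grid):
        n_edges = min(int(np.floor(s * m)), len(order))
        sel = order[:n_edges]
        stack[k, iu[sel], ju[sel]] = 1
        stack[k, ju[sel], iu[sel]] = 1
    return BinaryGraphEnsemble(subject_id=subject_id,
                               roi_names=tuple(roi_names),
                               sparsity_grid=grid, adjacency_stack=stack)


def individual_network(suvr_cn: SuvrMatrix, subject_row: pd.Series,
                       ren: ReferenceNetwork | None = None,
                       use_sqrt_denominator: bool = False) -> IndividualNetwork:
    """Convenience wrapper: perturbed network + Z-score for one subject."""
    ren = ren or build_reference_network(suvr_cn)
    cdn = build_perturbed_network(suvr_cn, subject_row)
    return perturbation_zscore(ren, cdn,
                               use_sqrt_denominator=use_sqrt_denominator)


def nodal_strength_table(nets: list[IndividualNetwork]) -> pd.DataFrame:
    """Subjects x ROI table of nodal strength (row sums of the Z matrix).

    The weighted-degree analogue on the individual Z network: the direct
    per-ROI aggregate of edge-level perturbations, used for ROI-wise
    group comparisons of connectivity change.
    """
    if not nets:
        raise ValueError("no networks given")
    rois = list(nets[0].roi_names)
    rows = {n.subject_id: n.z_matrix.sum(axis=1) for n in nets}
    return pd.DataFrame(rows, index=rois).T


def individual_networks(suvr: SuvrMatrix, labels: pd.Series,
                        reference_group: str = "CN",
                        use_sqrt_denominator: bool = False,
                        ) -> tuple[ReferenceNetwork, list[IndividualNetwork]]:
    """Individual Z networks for every subject in the table.

    The reference network is built from the ``reference_group`` subjects.
    Every subject — reference subjects included — is then added to the
    reference cohort one at a time (reference subjects therefore appear
    twice in their own perturbed network, mirroring the add-one-subject
    protocol).
    """
    labels = labels.reindex(suvr.values.index)
    if labels.isna().any():
        raise ValueError("labels do not cover all subjects")
    ref_ids = labels.index[labels == reference_group]
    if len(ref_ids) < 3:
        raise ValueError(f"reference group {reference_group!r} has "
                         f"{len(ref_ids)} subjects; need >= 3")
    ref = suvr.subset_subjects(ref_ids)
    ren = build_reference_network(ref)
    nets = [individual_network(ref, suvr.values.loc[sid], ren=ren,
                               use_sqrt_denominator=use_sqrt_denominator)
            for sid in suvr.values.index]
    return ren, nets
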