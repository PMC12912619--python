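"""Synthetic amyloid-PET cohorts with controlled covariance perturbations.

Regional SUVR vectors are drawn per diagnostic group from a multivariate
normal distribution.  Normality is the natural generative family here
because the downstream networks are Pearson correlations, which fully
characterize dependence under a Gaussian model.  Group-level disease
signal enters in two ways:

* mean shifts — per-group ROI mean vectors, calibrated by default to the
  published baseline compartment means (cerebellar 0.55 -> 0.63 and
  cortical 0.62 -> 0.88 from cognitively normal to Alzheimer's disease);
* covariance perturbations — selected inter-regional correlations are
  shifted on the correlation scale for a given group, then the matrix is
  projected back to the positive-semidefinite cone.  These injected edge
  shifts are the ground truth the perturbation Z-score network should
  recover.

Demographics (age, sex, MMSE) are drawn independently of the SUVR values
by default; an optional age slope couples SUVR to age so that covariate
adjustment has a nonzero ground truth to remove.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import CEREBELLAR, CORTICAL, RoiTemplate, default_template
from .suvr import SuvrMatrix

__all__ = [
    "GROUPS", "EdgePerturbation", "SyntheticSpec", "CohortTables",
    "default_correlation", "paper_cohort_spec", "inject_edge_perturbation",
    "generate_cohort", "generate_worked_fixture", "recovery_experiment_spec",
]

GROUPS = ("CN", "EMCI", "LMCI", "AD")

# Published baseline characteristics per group (non-PVEc):
# compartment-mean SUVR, age mean/SD, MMSE mean/SD, male fraction.
_GROUP_CEREBELLAR_MEAN = {"CN": 0.55, "EMCI": 0.58, "LMCI": 0.60, "AD": 0.63}
_GROUP_CORTICAL_MEAN = {"CN": 0.62, "EMCI": 0.70, "LMCI": 0.78, "AD": 0.88}
_GROUP_AGE = {"CN": (75.89, 7.97), "EMCI": (72.99, 7.04),
              "LMCI": (72.75, 7.37), "AD": (74.41, 8.40)}
_GROUP_MMSE = {"CN": (28.77, 1.67), "EMCI": (27.8, 4.26),
               "LMCI": (25.58, 3.56), "AD": (21.45, 4.26)}
_GROUP_MALE_FRACTION = {"CN": 98 / 172, "EMCI": 78 / 159,
                        "LMCI": 67 / 141, "AD": 82 / 140}
_GROUP_N = {"CN": 172, "EMCI": 159, "LMCI": 141, "AD": 140}

#: Per-ROI SUVR standard deviation (dimensionless).  Chosen so that the
#: per-subject compartment-mean SD matches the published interquartile
#: ranges (IQR ~ 0.08 for the cerebellar mean => SD ~ 0.06 of the mean of
#: strongly correlated ROIs => per-ROI SD ~ 0.08).
DEFAULT_ROI_SD = 0.08

_PSD_EIGEN_FLOOR = 1e-8


@dataclass(frozen=True)
class EdgePerturbation:
    """A correlation shift applied to one edge for one group."""

    group: str
    roi_i: str
    roi_j: str
    delta: float


@dataclass
class SyntheticSpec:
    """Full description of a synthetic cohort.

    ``group_means`` maps each group to a per-ROI mean vector;
    ``base_covariance`` is the shared ROI x ROI covariance;
    ``edge_perturbations`` lists group-specific correlation shifts applied
    on top of it.  ``noise_sd`` adds independent residual noise per ROI.
    """

    template: RoiTemplate
    n_per_group: dict[str, int]
    group_means: dict[str, np.ndarray]
    base_covariance: np.ndarray
    edge_perturbations: list[EdgePerturbation] = field(default_factory=list)
    noise_sd: float = 0.0
    age_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        r = self.template.n_rois
        cov = np.asarray(self.base_covariance, dtype=float)
        if cov.shape != (r, r):
            raise ValueError(f"base_covariance must be {r}x{r}")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("base_covariance must be symmetric")
        w = np.linalg.eigvalsh(cov)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError("base_covariance must be positive semidefinite")
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; allowed: {GROUPS}")
            if n < 3:
                raise ValueError(f"n_per_group[{g!r}] must be >= 3")
        for g, mu in self.group_means.items():
            if np.asarray(mu).shape != (r,):
                raise ValueError(f"group_means[{g!r}] must have length {r}")
        missing = set(self.n_per_group) - set(self.group_means)
        if missing:
            raise ValueError(f"no means for groups: {sorted(missing)}")
        for p in self.edge_perturbations:
            names = self.template.names
            if p.roi_i not in names or p.roi_j not in names:
                raise ValueError(f"perturbation edge ({p.roi_i}, {p.roi_j}) "
                                 "not in template")
            if abs(p.delta) > 1:
                raise ValueError("|delta_correlation| must be <= 1")

    def group_covariance(self, group: str) -> np.ndarray:
        """Base covariance with this group's edge perturbations applied."""
        edges = [(p.roi_i, p.roi_j, p.delta)
                 for p in self.edge_perturbations if p.group == group]
        if not edges:
            return np.asarray(self.base_covariance, dtype=float)
        names = list(self.template.names)
        idx_edges = [(names.index(i), names.index(j)) for i, j, _ in edges]
        deltas = [d for _, _, d in edges]
        return inject_edge_perturbation(self.base_covariance, idx_edges, deltas)


@dataclass
class CohortTables:
    """Generated SUVR matrix plus the demographics/label table."""

    suvr: SuvrMatrix
    demographics: pd.DataFrame   # index subject_id: group, age, sex, mmse

    def __post_init__(self) -> None:
        if not self.suvr.values.index.equals(self.demographics.index):
            raise ValueError("SUVR and demographics subject IDs differ")
        bad = set(self.demographics["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def labels(self) -> pd.Series:
        return self.demographics["group"]

    def write(self, suvr_path, demographics_path) -> None:
        self.suvr.to_csv(suvr_path)
        out = self.demographics.copy()
        out.index.name = "subject_id"
        out.to_csv(demographics_path)


def _cov_to_corr(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = np.sqrt(np.diag(cov))
    if (sd <= 0).any():
        raise ValueError("covariance has a zero-variance ROI")
    corr = cov / np.outer(sd, sd)
    return corr, sd


def nearest_psd_correlation(corr: np.ndarray,
                            eigen_floor: float = _PSD_EIGEN_FLOOR) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone by eigenvalue clipping,
    then rescale to unit diagonal."""
    corr = (corr + corr.T) / 2
    w, v = np.linalg.eigh(corr)
    if w.min() >= eigen_floor:
        return corr
    w = np.clip(w, eigen_floor, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2


def inject_edge_perturbation(cov: np.ndarray,
                             edges: list[tuple[int, int]],
                             deltas: float | list[float]) -> np.ndarray:
    """Shift selected correlations by the given deltas; keep the matrix PSD.

    The shift is applied on the correlation scale (so a delta of +0.3 means
    the edge correlation rises by 0.3 before projection), then the matrix
    is projected to the nearest PSD correlation by eigenvalue clipping and
    the original variances are restored.

    Raises
    ------
    IndexError   if an edge index is out of range.
    ValueError   if a shifted correlation leaves [-1, 1], or if the
                 projection cannot restore the requested shifts to within
                 0.5 of the target (perturbation inconsistent with PSD).
    """
    cov = np.asarray(cov, dtype=float)
    r = cov.shape[0]
    if np.isscalar(deltas):
        deltas = [float(deltas)] * len(edges)
    if len(deltas) != len(edges):
        raise ValueError("one delta per edge required")
    corr, sd = _cov_to_corr(cov)
    target = corr.copy()
    for (i, j), d in zip(edges, deltas):
        if not (0 <= i < r and 0 <= j < r):
            raise IndexError(f"edge index ({i}, {j}) out of range for "
                             f"{r} ROIs")
        if i == j:
            raise ValueError("cannot perturb a diagonal entry")
        new = corr[i, j] + d
        if abs(new) > 1:
            raise ValueError(
                f"perturbation drives correlation ({i}, {j}) to {new:.3f}, "
                "outside [-1, 1]")
        target[i, j] = target[j, i] = new
    projected = nearest_psd_correlation(target)
    for (i, j), d in zip(edges, deltas):
        if d != 0 and abs(projected[i, j] - target[i, j]) > 0.5 * abs(d):
            raise ValueError(
                "requested perturbation cannot be realized as a positive-"
                f"semidefinite matrix: edge ({i}, {j}) projected to "
                f"{projected[i, j]:.3f}, target {target[i, j]:.3f}")
    return projected * np.outer(sd, sd)


def default_correlation(template: RoiTemplate,
                        global_loading: float = 0.7,
                        compartment_loading: float = 0.35) -> np.ndarray:
    """Two-factor correlation structure for regional amyloid burden.

    One global factor (shared deposition level across the brain) plus one
    factor per compartment.  With the defaults, within-compartment
    correlations are ~0.61 and cross-compartment ~0.49, in line with the
    strong inter-regional covariance of amyloid SUVR.
    """
    tags = np.asarray(template.compartments)
    r = template.n_rois
    loadings = np.zeros((r, 3))
    loadings[:, 0] = global_loading
    loadings[:, 1] = np.where(tags == CEREBELLAR, compartment_loading, 0.0)
    loadings[:, 2] = np.where(tags == CORTICAL, compartment_loading, 0.0)
    corr = loadings @ loadings.T
    np.fill_diagonal(corr, 1.0)
    return corr


def _default_means(template: RoiTemplate, group: str) -> np.ndarray:
    """Per-ROI means: compartment mean plus a fixed deterministic spread.

    The published tables give compartment means only; a small fixed
    across-ROI gradient (+/- 0.04) stands in for regional heterogeneity.
    """
    mu = np.empty(template.n_rois)
    for tag, base in ((CEREBELLAR, _GROUP_CEREBELLAR_MEAN[group]),
                      (CORTICAL, _GROUP_CORTICAL_MEAN[group])):
        idx = [k for k, c in enumerate(template.compartments) if c == tag]
        if idx:
            mu[idx] = base + np.linspace(-0.04, 0.04, len(idx))
    return mu


def paper_cohort_spec(template: RoiTemplate | None = None,
                      n_per_group: dict[str, int] | None = None,
                      roi_sd: float = DEFAULT_ROI_SD,
                      edge_perturbations: list[EdgePerturbation] | None = None,
                      seed: int = 0) -> SyntheticSpec:
    """Cohort spec calibrated to the published baseline table.

    Defaults: group sizes 172/159/141/140 (CN/EMCI/LMCI/AD), cerebellar
    compartment means 0.55/0.58/0.60/0.63, cortical 0.62/0.70/0.78/0.88,
    per-ROI SD 0.08 and the two-factor correlation structure.
    """
    template = template or default_template()
    n_per_group = dict(n_per_group or _GROUP_N)
    corr = default_correlation(template)
    cov = corr * roi_sd ** 2
    means = {g: _default_means(template, g) for g in n_per_group}
    return SyntheticSpec(template=template, n_per_group=n_per_group,
                         group_means=means, base_covariance=cov,
                         edge_perturbations=list(edge_perturbations or []),
                         seed=seed)


def generate_cohort(spec: SyntheticSpec) -> CohortTables:
    """Draw the cohort described by *spec*.  Same spec + seed => identical
    tables, bit for bit."""
    rng = np.random.default_rng(spec.seed)
    frames, demo_rows = [], []
    for group in GROUPS:              # fixed order => stable draw sequence
        if group not in spec.n_per_group:
            continue
        n = spec.n_per_group[group]
        cov = spec.group_covariance(group)
        mu = np.asarray(spec.group_means[group], dtype=float)
        x = rng.multivariate_normal(mu, cov, size=n, method="cholesky")
        if spec.noise_sd > 0:
            x = x + rng.normal(0.0, spec.noise_sd, size=x.shape)
        age_mu, age_sd = _GROUP_AGE[group]
        age = rng.normal(age_mu, age_sd, size=n)
        if spec.age_slope != 0.0:
            x = x + spec.age_slope * (age - age_mu)[:, None]
        # SUVR must stay positive; with the default means/SDs the floor is
        # ~6 sigma away and essentially never binds.
        x = np.clip(x, 1e-3, None)
        male = rng.random(n) < _GROUP_MALE_FRACTION[group]
        mmse_mu, mmse_sd = _GROUP_MMSE[group]
        mmse = np.clip(np.round(rng.normal(mmse_mu, mmse_sd, size=n)), 0, 30)
        ids = [f"{group}_{k:04d}" for k in range(n)]
        frames.append(pd.DataFrame(x, index=ids,
                                   columns=list(spec.template.names)))
        demo_rows.append(pd.DataFrame({
            "group": group,
            "age": np.round(age, 1),
            "sex": np.where(male, "M", "F"),
            "mmse": mmse.astype(int),
        }, index=ids))
    values = pd.concat(frames)
    demo = pd.concat(demo_rows)
    suvr = SuvrMatrix(values, spec.template, correction="none")
    return CohortTables(suvr=suvr, demographics=demo)


def generate_worked_fixture(seed: int = 20240612) -> CohortTables:
    """Tiny fixed cohort (8 ROIs, 12 subjects per group) for fast
    end-to-end tests; deterministic for the default seed."""
    full = default_template()
    names = list(full.cerebellar_names[:4]) + list(full.cortical_names[:4])
    template = full.subset(names)
    spec = paper_cohort_spec(template=template,
                             n_per_group={g: 12 for g in GROUPS},
                             seed=seed)
    return generate_cohort(spec)


def _cerebellar_two_group_spec(n_per_group: int, perturbed_group: str,
                               perts: list[EdgePerturbation],
                               seed: int) -> SyntheticSpec:
    """CN + one patient group over the 26 cerebellar ROIs, with the patient
    group's mean vector set equal to CN's so that the injected covariance
    perturbation is the only group difference (pure connectivity signal)."""
    full = default_template()
    template = full.subset(list(full.cerebellar_names))
    spec = paper_cohort_spec(
        template=template,
        n_per_group={"CN": n_per_group, perturbed_group: n_per_group},
        edge_perturbations=perts, seed=seed)
    spec.group_means[perturbed_group] = spec.group_means["CN"].copy()
    return spec


def recovery_experiment_spec(n_per_group: int = 150,
                             delta: float = -0.3,
                             n_targets: int = 4,
                             perturbed_group: str = "AD",
                             seed: int = 0) -> tuple[SyntheticSpec, list[str]]:
    """Cohort in which ``n_targets`` cerebellar lobules are disconnected.

    Every edge incident to a target lobule is shifted by ``delta`` on the
    correlation scale in the patient group (the lobules decouple from the
    rest of the network), while the group mean vectors are identical — the
    connectivity change is the only signal.  Returns the spec and the
    targeted ROI names (the recovery ground truth).
    """
    full = default_template()
    names = list(full.cerebellar_names)
    targets = names[:n_targets]
    target_set = set(targets)
    perts = []
    for k, a in enumerate(names):
        for b in names[k + 1:]:
            if a in target_set or b in target_set:
                perts.append(EdgePerturbation(perturbed_group, a, b, delta))
    spec = _cerebellar_two_group_spec(n_per_group, perturbed_group, perts,
                                      seed)
    return spec, targets


def single_edge_recovery_spec(n_per_group: int = 150, delta: float = 0.3,
                              perturbed_group: str = "AD",
                              seed: int = 0,
                              ) -> tuple[SyntheticSpec, tuple[str, str]]:
    """Cohort with exactly one cerebellar edge shifted by ``delta`` in the
    patient group (group means identical).  Returns the spec and the
    perturbed edge."""
    full = default_template()
    names = list(full.cerebellar_names)
    edge = (names[0], names[1])
    perts = [EdgePerturbation(perturbed_group, *edge, delta)]
    spec = _cerebellar_two_group_spec(n_per_group, perturbed_group, perts,
                                      seed)
    return spec, edge


def null_experiment_spec(n_per_group: int = 150, group_b: str = "AD",
                         seed: int = 0) -> SyntheticSpec:
    """Two groups drawn from identical distributions (global null)."""
    return _cerebellar_two_group_spec(n_per_group, group_b, [], seed)
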