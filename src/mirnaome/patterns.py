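"""Library ordination (Z-score, PCA, HCA) and model-profile time-series
clustering in the style of the Short Time-series Expression Miner.

Model profiles over T time points start at 0 and change by at most one unit
(-c, 0, +c) per step; all 3^(T-1) candidates are enumerated, a maximally
distinct subset of m profiles is chosen greedily, each miRNA trajectory
(log2 ratio to the first stage) is assigned to its best-correlated profile,
and profile significance is a binomial tail against the expected assignment
count under exact enumeration of all T! permutations of the stage labels.
With the study design (T = 5 stages, c = 1, m = 20, P < 0.05) the whole
procedure is deterministic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import binom
from sklearn.decomposition import PCA

DEFAULT_MAX_PROFILES = 20
DEFAULT_UNIT_CHANGE = 1
DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    """PCA scores / variance fractions and the HCA dendrogram merge table."""

    scores: pd.DataFrame | None = None
    variance_ratio: pd.Series | None = None
    linkage_matrix: np.ndarray | None = None
    labels: list[str] = field(default_factory=list)


def zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardise each row to mean 0 and sample standard deviation 1.

    Rows with zero variance carry no clustering information and are dropped
    with a warning; an all-constant matrix is an error.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two libraries to standardise")
    sd = matrix.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.all():
        raise ValueError("all rows are constant; nothing to standardise")
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant rows", stacklevel=2
        )
    kept = matrix.loc[~constant]
    return kept.sub(kept.mean(axis=1), axis=0).div(sd[~constant], axis=0)


def pca_libraries(standardized: pd.DataFrame) -> OrdinationResult:
    """PCA with libraries as observations and miRNAs as variables.

    Components are ordered by decreasing variance; each component's sign is
    fixed so its largest-magnitude loading is positive, making scores
    reproducible across linear-algebra backends.
    """
    if standardized.shape[1] < 2:
        raise ValueError("need at least two libraries for PCA")
    obs = standardized.T.to_numpy(dtype=float)  # libraries x miRNAs
    n_comp = min(obs.shape[0], obs.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(obs)
    for k in range(n_comp):
        pivot = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, pivot] < 0:
            pca.components_[k] *= -1
            scores[:, k] *= -1
    labels = list(standardized.columns)
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=labels, columns=comp_names),
        variance_ratio=pd.Series(pca.explained_variance_ratio_, index=comp_names),
        labels=labels,
    )


def correlation_distance_matrix(standardized: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between library columns."""
    corr = np.corrcoef(standardized.T.to_numpy(dtype=float))
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d[d < 0] = 0.0  # clip tiny negative rounding residue
    return pd.DataFrame(d, index=standardized.columns, columns=standardized.columns)


def average_linkage(distance: pd.DataFrame) -> np.ndarray:
    """Agglomerative average-linkage merge table for a square distance matrix."""
    condensed = squareform(distance.to_numpy(dtype=float), checks=False)
    return linkage(condensed, method="average")


def hcluster_libraries(standardized: pd.DataFrame) -> OrdinationResult:
    """Average-linkage HCA of libraries on 1 - Pearson correlation distance.

    Columns are processed in lexicographic library-id order, which fixes the
    tie-break for equal-distance merges.
    """
    ordered = standardized[sorted(standardized.columns)]
    dist = correlation_distance_matrix(ordered)
    return OrdinationResult(
        linkage_matrix=average_linkage(dist), labels=list(ordered.columns)
    )


def dendrogram_newick(result: OrdinationResult) -> str:
    """Newick export of an HCA dendrogram (branch lengths from merge heights)."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(result.linkage_matrix)

    def render(node) -> str:
        if node.is_leaf():
            return result.labels[node.id]
        left, right = node.get_left(), node.get_right()
        parts = []
        for child in (left, right):
            length = node.dist - (0.0 if child.is_leaf() else child.dist)
            parts.append(f"{render(child)}:{length:.6g}")
        return f"({','.join(parts)})"

    return render(tree) + ";"


# ---------------------------------------------------------------------------
# model profiles
# ---------------------------------------------------------------------------


@dataclass
class ModelProfile:
    """One temporal model profile and, after assignment, its statistics."""

    profile_id: int
    steps: tuple[int, ...]
    values: tuple[float, ...]
    assigned: list[str] = field(default_factory=list)
    expected: float | None = None
    p_value: float | None = None
    significant: bool | None = None

    @property
    def is_flat(self) -> bool:
        return all(s == 0 for s in self.steps)


def _profile_correlation(vec: np.ndarray, values: np.ndarray) -> float:
    """Pearson correlation; any constant vector (the flat profile, or a flat
    trajectory) has undefined correlation, taken as 0 by convention."""
    if np.ptp(vec) == 0 or np.ptp(values) == 0:
        return 0.0
    return float(np.corrcoef(vec, values)[0, 1])


def stem_enumerate(
    n_stages: int, unit_change: int = DEFAULT_UNIT_CHANGE
) -> list[tuple[float, ...]]:
    """All 3^(T-1) candidate profiles: cumulative sums of steps in
    {-c, 0, +c}, starting at 0, in lexicographic step order."""
    if n_stages < 2:
        raise ValueError("need at least two time points")
    if unit_change < 1:
        raise ValueError("unit change must be >= 1")
    candidates = []
    for steps in itertools.product(
        (-unit_change, 0, unit_change), repeat=n_stages - 1
    ):
        values = (0.0, *np.cumsum(steps).astype(float))
        candidates.append((steps, values))
    return candidates


def stem_select(
    candidates: list[tuple[tuple[int, ...], tuple[float, ...]]],
    max_profiles: int = DEFAULT_MAX_PROFILES,
) -> list[ModelProfile]:
    """Greedy max-min selection of ``max_profiles`` distinct profiles.

    Starts from the profile with the largest absolute total change (ties by
    lexicographically smallest step sequence), then repeatedly adds the
    candidate whose minimum 1 - correlation distance to the selected set is
    largest (same tie-break). Fully deterministic.
    """
    if max_profiles > len(candidates):
        raise ValueError("cannot select more profiles than candidates")
    arrs = [np.asarray(values) for _, values in candidates]

    def dist(i: int, j: int) -> float:
        return 1.0 - _profile_correlation(arrs[i], arrs[j])

    order = sorted(
        range(len(candidates)),
        key=lambda i: (-abs(arrs[i][-1] - arrs[i][0]), candidates[i][0]),
    )
    selected = [order[0]]
    remaining = [i for i in range(len(candidates)) if i != order[0]]
    while len(selected) < max_profiles:
        best_i, best_key = None, None
        for i in remaining:
            min_d = min(dist(i, j) for j in selected)
            key = (-min_d, candidates[i][0])
            if best_key is None or key < best_key:
                best_i, best_key = i, key
        selected.append(best_i)
        remaining.remove(best_i)
    return [
        ModelProfile(
            profile_id=pid, steps=candidates[i][0], values=candidates[i][1]
        )
        for pid, i in enumerate(selected)
    ]


def trajectory_transform(stage_tpm: pd.DataFrame) -> pd.DataFrame:
    """log2 ratio of each stage to the first stage (revised TPM input, so
    every value is positive and the first column is identically 0)."""
    if (stage_tpm.to_numpy() <= 0).any():
        raise ValueError("trajectories require positive (revised) TPM values")
    return np.log2(stage_tpm.div(stage_tpm.iloc[:, 0], axis=0))


def _assign_matrix(
    traj: np.ndarray, profiles: list[ModelProfile]
) -> np.ndarray:
    """Profile index per trajectory row (max correlation, ties to the lower
    profile id, constant trajectories to the flat profile)."""
    flat_idx = next(
        (k for k, p in enumerate(profiles) if p.is_flat), None
    )
    prof = np.array([p.values for p in profiles], dtype=float)
    pm = prof - prof.mean(axis=1, keepdims=True)
    pn = np.linalg.norm(pm, axis=1)
    tm = traj - traj.mean(axis=1, keepdims=True)
    tn = np.linalg.norm(tm, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (tm @ pm.T) / np.outer(tn, pn)
    corr[~np.isfinite(corr)] = 0.0  # flat profile or flat trajectory
    out = np.argmax(corr, axis=1)  # argmax takes the lowest index on ties
    if flat_idx is not None:
        out[tn == 0] = flat_idx
    return out


def stem_assign(
    stage_tpm: pd.DataFrame, profiles: list[ModelProfile]
) -> list[ModelProfile]:
    """Assign each miRNA trajectory to its best-matching model profile."""
    traj = trajectory_transform(stage_tpm).to_numpy(dtype=float)
    idx = _assign_matrix(traj, profiles)
    out = [
        ModelProfile(p.profile_id, p.steps, p.values) for p in profiles
    ]
    for row, k in zip(stage_tpm.index, idx):
        out[k].assigned.append(row)
    return out


def stem_significance(
    profiles: list[ModelProfile],
    stage_tpm: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> list[ModelProfile]:
    """Exact-permutation expected counts and binomial enrichment p-values.

    For every one of the T! permutations of the stage labels, each miRNA's
    permuted trajectory is re-assigned; a profile's expected count is the
    mean assignment count over permutations. The p-value is the binomial
    tail P(X >= observed) with n = number of miRNAs and p = expected / n,
    Bonferroni-corrected across profiles; the significant flag applies the
    corrected threshold ``alpha``. At T = 5 this enumerates all 120
    permutations, so there is no sampling randomness.
    """
    values = stage_tpm.to_numpy(dtype=float)
    n_mirnas, n_stages = values.shape
    m = len(profiles)
    totals = np.zeros(m, dtype=float)
    n_perms = 0
    for perm in itertools.permutations(range(n_stages)):
        permuted = values[:, perm]
        traj = np.log2(permuted / permuted[:, [0]])
        idx = _assign_matrix(traj, profiles)
        totals += np.bincount(idx, minlength=m)
        n_perms += 1
    expected = totals / n_perms

    observed = np.array([len(p.assigned) for p in profiles])
    out = []
    for k, p in enumerate(profiles):
        rate = min(1.0, expected[k] / n_mirnas) if n_mirnas else 0.0
        pval = float(binom.sf(observed[k] - 1, n_mirnas, rate))
        corrected = min(1.0, pval * m)
        out.append(
            ModelProfile(
                profile_id=p.profile_id,
                steps=p.steps,
                values=p.values,
                assigned=list(p.assigned),
                expected=float(expected[k]),
                p_value=corrected,
                significant=bool(corrected < alpha),
            )
        )
    return out


def profile_table(profiles: list[ModelProfile]) -> pd.DataFrame:
    """Tabular view of profiles: shape, observed/expected counts, p, flag."""
    return pd.DataFrame(
        {
            "profile_id": [p.profile_id for p in profiles],
            "values": [",".join(f"{v:g}" for v in p.values) for p in profiles],
            "observed": [len(p.assigned) for p in profiles],
            "expected": [p.expected for p in profiles],
            "p_value": [p.p_value for p in profiles],
            "significant": [p.significant for p in profiles],
        }
    ).set_index("profile_id")


def run_stem(
    stage_tpm: pd.DataFrame,
    max_profiles: int = DEFAULT_MAX_PROFILES,
    unit_change: int = DEFAULT_UNIT_CHANGE,
    alpha: float = DEFAULT_ALPHA,
) -> list[ModelProfile]:
    """Enumerate, select, assign and score model profiles for one breed."""
    candidates = stem_enumerate(stage_tpm.shape[1], unit_change)
    profiles = stem_select(candidates, max_profiles)
    profiles = stem_assign(stage_tpm, profiles)
    return stem_significance(profiles, stage_tpm, alpha=alpha)
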