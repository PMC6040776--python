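"""Exact tag-count test (Audic-Claverie) and the fold-change + P screen.

For a tag observed x times in library 1 (N1 total clean reads) and y times
in library 2 (N2), the probability of y conditional on x under equal
underlying concentration is

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1),

computed in log space via log-gamma. Tail p-values are the cumulative sums
C(y <= y_obs | x) and D(y >= y_obs | x); the upper tail uses the complement
of the finite lower sum so no infinite summation is needed. A miRNA is
called differentially expressed when |log2 fold change| on revised TPM
exceeds log2(2) and the two-sided P (doubled minimum tail, capped at 1)
falls below 0.05 — the fold and P criteria of the screen, both strict.

Stage-DE compares neighbouring developmental stages within a breed;
breed-DE compares the two breeds at the same stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .quantify import ExpressionMatrix

DEFAULT_FOLD = 2.0
DEFAULT_P = 0.05


def _validate(x: int, y: int, n1: float, n2: float) -> None:
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if int(x) != x or int(y) != y:
        raise ValueError("counts must be integers")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")


def ac_log_pmf(y, x, n1: float, n2: float):
    """log p(y | x) for scalar or array y (vectorised over y)."""
    y = np.asarray(y, dtype=float)
    r = n2 / n1
    return (
        y * np.log(r)
        + gammaln(x + y + 1.0)
        - gammaln(x + 1.0)
        - gammaln(y + 1.0)
        - (x + y + 1.0) * np.log1p(r)
    )


def ac_point_probability(x: int, y: int, n1: float, n2: float) -> float:
    """Point probability p(y | x) of the exact tag-count test."""
    _validate(x, y, n1, n2)
    return float(np.exp(ac_log_pmf(y, x, n1, n2)))


def _upper_tail_direct(x: int, y_obs: int, n1: float, n2: float) -> float:
    """Forward summation of the upper tail from y_obs.

    Used when the complement form loses all precision (tiny upper tails,
    where y_obs is far above the mode so terms decrease geometrically).
    """
    r = n2 / n1
    log_first = float(ac_log_pmf(y_obs, x, n1, n2))
    total = 1.0  # in units of the first term
    term = 1.0
    y = y_obs
    while term > total * 1e-18 and y < y_obs + 1_000_000:
        term *= r * (x + y + 1.0) / ((y + 1.0) * (1.0 + r))
        total += term
        y += 1
    return float(np.exp(log_first) * total)


def ac_tail_pvalues(
    x: int, y_obs: int, n1: float, n2: float
) -> tuple[float, float, float]:
    """(p_upper, p_lower, p_two_sided) for an observed pair (x, y_obs).

    p_lower = sum_{y=0}^{y_obs} p(y|x); p_upper = 1 - sum_{y<y_obs} p(y|x)
    (both tails include the observed point, so p_upper + p_lower >= 1);
    p_two_sided = min(1, 2 * min(p_upper, p_lower)). The complement form of
    the upper tail avoids infinite summation; when it underflows the tail
    is recomputed by direct summation so p-values never collapse to zero.
    """
    _validate(x, y_obs, n1, n2)
    lp = ac_log_pmf(np.arange(y_obs + 1), x, n1, n2)
    p_lower = min(1.0, float(np.exp(logsumexp(lp))))
    if y_obs == 0:
        p_upper = 1.0
    else:
        p_upper = float(-np.expm1(logsumexp(lp[:-1])))
        if p_upper < 1e-8:  # complement lost precision
            p_upper = _upper_tail_direct(x, y_obs, n1, n2)
    p_two = min(1.0, 2.0 * min(p_upper, p_lower))
    return p_upper, p_lower, p_two


def ac_tails_batch(x, y, n1: float, n2: float):
    """Vectorised tails over paired count arrays (one comparison).

    Returns (p_upper, p_lower, p_two_sided) arrays. Builds the p(y'|x_i)
    grid up to max(y) once, so memory is O(len(x) * max(y)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    max_y = int(y.max()) if y.size else 0
    grid = np.arange(max_y + 1, dtype=float)
    lp = ac_log_pmf(grid[None, :], x[:, None], n1, n2)
    # running log-sum-exp along y'
    clp = np.logaddexp.accumulate(lp, axis=1)
    rows = np.arange(x.size)
    p_lower = np.minimum(1.0, np.exp(clp[rows, y]))
    p_upper = np.ones_like(p_lower)
    nz = y > 0
    p_upper[nz] = -np.expm1(clp[rows[nz], y[nz] - 1])
    for i in np.flatnonzero(nz & (p_upper < 1e-8)):
        p_upper[i] = _upper_tail_direct(int(x[i]), int(y[i]), n1, n2)
    p_two = np.minimum(1.0, 2.0 * np.minimum(p_upper, p_lower))
    return p_upper, p_lower, p_two


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


@dataclass
class DEComparison:
    """One miRNA in one comparison: counts, totals, fold and verdict."""

    label: str
    mirna_id: str
    x: int
    y: int
    n1: float
    n2: float
    tpm_a: float
    tpm_b: float
    log2_ratio: float
    p_upper: float
    p_lower: float
    p_two_sided: float
    is_de: bool
    direction: str  # "up" when condition B exceeds A


def compare_counts(
    label: str,
    mirna_id: str,
    x: int,
    y: int,
    n1: float,
    n2: float,
    tpm_a: float,
    tpm_b: float,
    fold_threshold: float = DEFAULT_FOLD,
    p_threshold: float = DEFAULT_P,
) -> DEComparison:
    """Exact test plus the fold gate for a single count pair."""
    p_upper, p_lower, p_two = ac_tail_pvalues(x, y, n1, n2)
    log2_ratio = float(np.log2(tpm_b / tpm_a))
    is_de = abs(log2_ratio) > np.log2(fold_threshold) and p_two < p_threshold
    return DEComparison(
        label=label,
        mirna_id=mirna_id,
        x=x,
        y=y,
        n1=n1,
        n2=n2,
        tpm_a=tpm_a,
        tpm_b=tpm_b,
        log2_ratio=log2_ratio,
        p_upper=p_upper,
        p_lower=p_lower,
        p_two_sided=p_two,
        is_de=bool(is_de),
        direction="up" if log2_ratio > 0 else "down",
    )


def _comparisons(matrix: ExpressionMatrix, mode: str):
    """(label, lib_a, lib_b, breed_or_None, stage_or_None) comparison plan."""
    if not matrix.metas:
        raise ValueError("library metadata required for screening")
    metas = list(matrix.metas.values())
    breeds = sorted({m.breed for m in metas})
    stages = sorted({m.stage for m in metas})
    lookup = {(m.breed, m.stage): m.library_id for m in metas}
    plan = []
    if mode == "breed":
        if len(breeds) != 2:
            raise ValueError("breed mode needs exactly two breeds")
        a_breed, b_breed = breeds
        for stage in stages:
            try:
                la, lb = lookup[(a_breed, stage)], lookup[(b_breed, stage)]
            except KeyError as exc:
                raise ValueError(f"missing library for stage {stage}") from exc
            plan.append((f"{la}-vs-{lb}", la, lb, None, stage))
    elif mode == "stage":
        for breed in breeds:
            for s1, s2 in zip(stages, stages[1:]):
                try:
                    la, lb = lookup[(breed, s1)], lookup[(breed, s2)]
                except KeyError as exc:
                    raise ValueError(f"missing library for {breed}") from exc
                plan.append((f"{la}-vs-{lb}", la, lb, breed, None))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return plan


def screen_de(
    matrix: ExpressionMatrix,
    mode: str = "breed",
    fold_threshold: float = DEFAULT_FOLD,
    p_threshold: float = DEFAULT_P,
) -> pd.DataFrame:
    """Run the exact-test screen over all miRNAs and comparisons.

    mode="breed": the same-stage comparisons (one per stage, breed A vs B);
    mode="stage": the neighbour-stage comparisons within each breed. Input
    should be the high-expression-filtered matrix. Returns one row per
    (miRNA, comparison) with every DEComparison field.
    """
    if matrix.tpm is None:
        raise ValueError("TPM layer not populated; call tpm_normalize first")
    rows = []
    log2_gate = np.log2(fold_threshold)
    for label, la, lb, breed, stage in _comparisons(matrix, mode):
        x = matrix.counts[la].to_numpy()
        y = matrix.counts[lb].to_numpy()
        n1 = float(matrix.totals[la])
        n2 = float(matrix.totals[lb])
        tpm_a = matrix.tpm[la].to_numpy()
        tpm_b = matrix.tpm[lb].to_numpy()
        p_upper, p_lower, p_two = ac_tails_batch(x, y, n1, n2)
        log2_ratio = np.log2(tpm_b / tpm_a)
        is_de = (np.abs(log2_ratio) > log2_gate) & (p_two < p_threshold)
        for i, mirna in enumerate(matrix.counts.index):
            rows.append(
                {
                    "mirna_id": mirna,
                    "label": label,
                    "breed": breed,
                    "stage": stage,
                    "x": int(x[i]),
                    "y": int(y[i]),
                    "n1": n1,
                    "n2": n2,
                    "tpm_a": tpm_a[i],
                    "tpm_b": tpm_b[i],
                    "log2_ratio": log2_ratio[i],
                    "p_upper": p_upper[i],
                    "p_lower": p_lower[i],
                    "p_two_sided": p_two[i],
                    "is_de": bool(is_de[i]),
                    "direction": "up" if log2_ratio[i] > 0 else "down",
                }
            )
    return pd.DataFrame(rows)


def breed_de_sets(screen: pd.DataFrame) -> dict[int, set[str]]:
    """DE miRNA ids per stage from a breed-mode screen table."""
    de = screen[screen["is_de"]]
    return {
        int(stage): set(group["mirna_id"])
        for stage, group in de.groupby("stage")
    }


def stage_de_sets(screen: pd.DataFrame) -> dict[str, set[str]]:
    """Union of DE miRNA ids per breed from a stage-mode screen table."""
    de = screen[screen["is_de"]]
    return {
        str(breed): set(group["mirna_id"])
        for breed, group in de.groupby("breed")
    }


def de_set_algebra(
    set_a: set[str], set_b: set[str], screen: pd.DataFrame | None = None
) -> dict:
    """Set sizes, intersection, and per-comparison up/down tallies."""
    out = {
        "n_a": len(set_a),
        "n_b": len(set_b),
        "shared": len(set_a & set_b),
        "shared_ids": sorted(set_a & set_b),
    }
    if screen is not None:
        de = screen[screen["is_de"]]
        tallies = (
            de.groupby(["label", "direction"]).size().unstack(fill_value=0)
        )
        for col in ("up", "down"):
            if col not in tallies:
                tallies[col] = 0
        out["per_comparison"] = tallies[["up", "down"]]
    return out
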