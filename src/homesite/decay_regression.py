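"""Distance-decay of community similarity with host evolutionary divergence.

Host-associated communities resemble each other less the longer ago their
hosts diverged. This module assembles all pairwise sample similarities
against host divergence times t (in millions of years, Ma; within-line pairs
sit at t = 0) and fits the two-parameter exponential decay

    S(t) = a * exp(-b * t)

by nonlinear least squares, initialised from the log-linear regression of
log S on t. R-squared is computed on the similarity scale and the p-value
from an F-test of the fitted curve against the constant-mean model. No
asymptote term is fitted; residual diagnostics are left to the caller.
Pairwise distances share samples and are therefore not independent; the fit
ignores this (the conventional presentation), and a permutation p-value is
available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform

from homesite.community_io import FeatureTable

__all__ = ["DecayFit", "pairwise_decay_input", "fit_exponential_decay"]


@dataclass(frozen=True)
class DecayFit:
    """Exponential decay fit S = a * exp(-b t) of similarity on divergence time."""

    a: float  # similarity intercept at divergence 0
    b: float  # decay rate per million years
    se_a: float
    se_b: float
    r_squared: float
    p_value: float
    n_pairs: int


def _pair_category(
    line_a: str, line_b: str, taxonomy: pd.DataFrame | None
) -> str:
    if line_a == line_b:
        return "within_line"
    if taxonomy is None:
        return "between_line"
    tax = taxonomy.set_index("line") if "line" in taxonomy.columns else taxonomy
    sp_a, sp_b = tax.at[line_a, "species"], tax.at[line_b, "species"]
    if sp_a == sp_b:
        return "between_line_within_species"
    if "genus" in tax.columns and tax.at[line_a, "genus"] == tax.at[line_b, "genus"]:
        return "between_species"
    return "between_genera"


def pairwise_decay_input(
    table: FeatureTable,
    sample_lines: pd.Series,
    divergence_table: pd.DataFrame,
    metric: str = "jaccard",
    detection_min: int = 1,
    line_taxonomy: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """All unordered sample pairs with similarity, divergence time and category.

    Parameters
    ----------
    sample_lines : Series
        Host line of each sample (index = sample id); only samples listed
        here enter the pairing.
    divergence_table : DataFrame
        Columns ``line_a``, ``line_b``, ``divergence_ma`` giving host
        divergence time in Ma for every between-line pair (either order);
        within-line pairs are fixed at t = 0 and need no entry. A missing
        between-line entry is an error naming the pair.
    line_taxonomy : DataFrame, optional
        Columns ``line``, ``species`` (and optionally ``genus``): refines
        the comparison category into within line / between line-within
        species / between species / between genera.

    Returns a frame with columns sample_a, sample_b, line_a, line_b,
    similarity, divergence_ma, category — n(n-1)/2 rows for n samples.
    """
    samples = [s for s in table.sample_ids if s in sample_lines.index]
    missing = set(sample_lines.index) - set(table.sample_ids)
    if missing:
        raise KeyError(f"samples in line map but not in table: {sorted(missing)}")
    sub = table.select_samples(samples)
    if metric == "jaccard":
        mat = sub.presence(detection_min).to_numpy().T  # samples x ASVs
        sim = 1.0 - squareform(pdist(mat, metric="jaccard"))
    elif metric == "bray_curtis":
        mat = sub.relative_abundance().to_numpy().T
        sim = 1.0 - squareform(pdist(mat, metric="braycurtis"))
    else:
        raise ValueError(f"metric must be 'jaccard' or 'bray_curtis', got {metric!r}")

    lookup: dict[frozenset, float] = {}
    for row in divergence_table.itertuples():
        lookup[frozenset((str(row.line_a), str(row.line_b)))] = float(row.divergence_ma)

    records = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            la, lb = str(sample_lines[samples[i]]), str(sample_lines[samples[j]])
            if la == lb:
                t = 0.0
            else:
                key = frozenset((la, lb))
                if key not in lookup:
                    raise KeyError(f"no divergence time for host-line pair ({la}, {lb})")
                t = lookup[key]
            records.append(
                {
                    "sample_a": samples[i],
                    "sample_b": samples[j],
                    "line_a": la,
                    "line_b": lb,
                    "similarity": float(sim[i, j]),
                    "divergence_ma": t,
                    "category": _pair_category(la, lb, line_taxonomy),
                }
            )
    return pd.DataFrame(records)


def _decay(t: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * np.exp(-b * t)


def fit_exponential_decay(pairs: pd.DataFrame, permutations: int = 0, seed: int | None = None) -> DecayFit:
    """Fit S = a * exp(-b t) to (similarity, divergence) pairs.

    ``pairs`` needs columns ``similarity`` (in (0, 1]) and ``divergence_ma``.
    The fit is initialised from the ordinary least-squares regression of
    log S on t and refined by nonlinear least squares on the similarity
    scale. The default p-value is the F-test of the fitted two-parameter
    model against the constant mean; with ``permutations`` > 0 it is instead
    the fraction of divergence-time permutations achieving an R-squared at
    least as large (an approximation that permutes pair labels, not
    samples, so shared-sample dependence is not fully honoured).
    """
    s = np.asarray(pairs["similarity"], dtype=float)
    t = np.asarray(pairs["divergence_ma"], dtype=float)
    n = s.size
    if n < 3 or np.unique(t).size < 3:
        raise ValueError("need at least 3 pairs spanning at least 3 distinct divergence times")
    if (s <= 0).any() or (s > 1).any():
        raise ValueError("similarities must lie in (0, 1] for the log-linear initialiser")

    slope, intercept = np.polyfit(t, np.log(s), 1)
    a0, b0 = float(np.exp(intercept)), float(-slope)
    try:
        popt, pcov = optimize.curve_fit(_decay, t, s, p0=(a0, b0), maxfev=10_000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"decay fit did not converge (initialiser a0={a0:.4g}, b0={b0:.4g}): {exc}"
        ) from None
    a, b = float(popt[0]), float(popt[1])
    se_a, se_b = (float(np.sqrt(v)) if np.isfinite(v) and v >= 0 else float("nan") for v in np.diag(pcov))

    resid = s - _decay(t, a, b)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r_squared = float(np.clip(r_squared, 0.0, 1.0))

    if b < 0:
        warnings.warn(
            f"fitted decay rate is negative (b={b:.4g}): similarity increases with divergence",
            stacklevel=2,
        )

    if permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(permutations):
            tp = rng.permutation(t)
            try:
                popt_p, _ = optimize.curve_fit(_decay, tp, s, p0=(a0, b0), maxfev=2_000)
                rp = 1.0 - np.sum((s - _decay(tp, *popt_p)) ** 2) / ss_tot if ss_tot > 0 else 0.0
            except RuntimeError:
                rp = 0.0
            if rp >= r_squared - 1e-12:
                hits += 1
        p_value = (hits + 1) / (permutations + 1)
    elif ss_tot <= 0 or ss_res >= ss_tot:
        p_value = 1.0
    elif ss_res == 0:
        p_value = 0.0
    else:
        f_stat = ((ss_tot - ss_res) / 1.0) / (ss_res / (n - 2))
        p_value = float(stats.f.sf(f_stat, 1, n - 2))

    return DecayFit(a, b, se_a, se_b, r_squared, float(p_value), n)
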