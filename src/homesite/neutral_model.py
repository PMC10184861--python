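"""Neutral community assembly of a two-donor mixture, weighted by bacterial load.

Under neutral assembly the probability that a read in a recipient community
derives from ASV i is fixed entirely by propagule pressure: each donor's
relative-abundance profile blended by the fraction of the inoculum's total
16S copies that donor contributed,

    w = L_nat * m_nat / (L_nat * m_nat + L_non * m_non)
    p_i = w * p_i^native + (1 - w) * p_i^nonnative

where L is load (16S copies per gram, from qPCR) and m the grams of feces
mixed in. A simulated recipient is a multinomial draw of ``depth`` reads
from p, modelling sequencing from an effectively infinite inoculum pool.
The expected LAI is the Monte-Carlo mean LAI of such simulated recipients
against the two donors; the per-ASV expected relative abundances are the
mixture probabilities themselves. Observed minus expected LAI is the test
statistic for competitive advantage of the native community beyond
neutrality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from homesite.community_io import DonorSample, FeatureTable
from homesite.similarity import METRICS, LaiRecord, _align_profiles, _normalise, batch_lai

__all__ = [
    "MixtureDesign",
    "NeutralExpectation",
    "donor_weight",
    "mixture_probabilities",
    "simulate_neutral_community",
    "expected_lai",
    "lai_deviation",
    "expected_asv_abundance",
]


def donor_weight(
    load_native: float,
    mass_native: float,
    load_nonnative: float,
    mass_nonnative: float,
) -> float:
    """Native donor's fractional share of the inoculum's total microbial load.

    Each donor contributes load x mass total 16S copies; the weight is the
    native donor's share of the combined total and lies strictly in (0, 1).
    """
    for name, value in (
        ("load_native", load_native),
        ("mass_native", mass_native),
        ("load_nonnative", load_nonnative),
        ("mass_nonnative", mass_nonnative),
    ):
        if not (value > 0 and np.isfinite(value)):
            raise ValueError(f"{name} must be positive and finite, got {value!r}")
    native_copies = load_native * mass_native
    nonnative_copies = load_nonnative * mass_nonnative
    return native_copies / (native_copies + nonnative_copies)


@dataclass(frozen=True)
class MixtureDesign:
    """A (native donor, non-native donor) inoculum pair with its mixing weight."""

    inoculum_id: str
    native: DonorSample
    nonnative: DonorSample

    @property
    def weight_native(self) -> float:
        """w, the native donor's fraction of the mixture's total 16S copies."""
        return donor_weight(self.native.load, self.native.mass, self.nonnative.load, self.nonnative.mass)


def mixture_probabilities(native_profile, nonnative_profile, w: float):
    """Per-ASV assembly probabilities of the load-weighted donor mixture.

    Profiles (counts or relative abundances on a shared ASV universe; pandas
    Series are aligned on their index union) are normalised to sum to 1 and
    blended as ``w * p_native + (1 - w) * p_nonnative``. Returns a vector
    summing to 1, as a Series when both inputs are Series.
    """
    if not (0.0 <= w <= 1.0):
        raise ValueError(f"w must lie in [0, 1], got {w!r}")
    as_series = isinstance(native_profile, pd.Series) and isinstance(nonnative_profile, pd.Series)
    (nat, non), universe = _align_profiles(native_profile, nonnative_profile)
    probs = w * _normalise(nat, "native profile") + (1.0 - w) * _normalise(non, "non-native profile")
    probs /= probs.sum()  # cancel last-ulp drift
    if as_series:
        return pd.Series(probs, index=universe)
    return probs


def expected_asv_abundance(native_profile, nonnative_profile, w: float):
    """Expected relative abundance of every ASV under neutral assembly.

    Identical to :func:`mixture_probabilities`; exposed under the name the
    per-ASV selection tests use for their null expectation.
    """
    return mixture_probabilities(native_profile, nonnative_profile, w)


def simulate_neutral_community(
    probs,
    depth: int,
    n_reps: int,
    seed: int | np.random.Generator | None = None,
    sample_prefix: str = "neutral",
) -> FeatureTable:
    """Simulate ``n_reps`` recipient communities under neutral assembly.

    Each replicate is an independent multinomial draw of ``depth`` reads
    from the assembly probability vector ``probs``. Columns are named
    ``<sample_prefix>_rep<k>`` and each sums to exactly ``depth``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    index = probs.index if isinstance(probs, pd.Series) else pd.RangeIndex(len(probs)).astype(str)
    p = np.asarray(probs, dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probs must be a probability vector summing to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.multinomial(depth, p / p.sum(), size=n_reps)  # (n_reps, n_asvs)
    frame = pd.DataFrame(
        draws.T, index=index, columns=[f"{sample_prefix}_rep{k}" for k in range(n_reps)]
    )
    return FeatureTable(frame)


@dataclass
class NeutralExpectation:
    """Monte-Carlo expectation of recipient composition and LAI under neutrality."""

    inoculum_id: str | None
    metric: str
    depth: int
    n_reps: int
    seed: int | None
    mixture_probs: np.ndarray = field(repr=False)
    lai_distribution: np.ndarray = field(repr=False)
    asv_ids: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mixture_probs = np.asarray(self.mixture_probs, dtype=float)
        self.lai_distribution = np.asarray(self.lai_distribution, dtype=float)
        if abs(self.mixture_probs.sum() - 1.0) > 1e-9:
            raise ValueError("mixture_probs must sum to 1")
        if len(self.lai_distribution) != self.n_reps:
            raise ValueError("lai_distribution length must equal n_reps")
        if not (-1.0 - 1e-12 <= self.expected_lai <= 1.0 + 1e-12):
            raise ValueError("expected LAI outside [-1, 1]")

    @property
    def expected_lai(self) -> float:
        """Mean LAI over the simulated neutral recipients."""
        return float(self.lai_distribution.mean())

    @property
    def sd_lai(self) -> float:
        """Standard deviation of the simulated LAI distribution."""
        return float(self.lai_distribution.std(ddof=1)) if self.n_reps > 1 else float("nan")

    @property
    def expected_asv_relabund(self):
        """Expected per-ASV relative abundance (the mixture probabilities)."""
        if self.asv_ids is not None:
            return pd.Series(self.mixture_probs, index=self.asv_ids)
        return self.mixture_probs.copy()


def expected_lai(
    recipient_depth: int,
    native_profile,
    nonnative_profile,
    w: float,
    n_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
    metric: str = "jaccard",
    inoculum_id: str | None = None,
) -> NeutralExpectation:
    """Expected LAI of a recipient sequenced at ``recipient_depth`` under neutrality.

    Simulates ``n_reps`` neutral recipients at the observed recipient's read
    depth, computes each one's LAI against the two (full, un-subsampled)
    donor profiles, and summarises the distribution. ``recipient_depth``
    should match the observed sample's depth so that richness lost to finite
    sequencing is reflected in the null.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 to estimate a distribution")
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    as_series = isinstance(native_profile, pd.Series) and isinstance(nonnative_profile, pd.Series)
    (nat, non), universe = _align_profiles(native_profile, nonnative_profile)
    probs = mixture_probabilities(nat, non, w)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.multinomial(recipient_depth, probs, size=n_reps)
    lai_values = batch_lai(draws, nat, non, metric=metric)
    return NeutralExpectation(
        inoculum_id=inoculum_id,
        metric=metric,
        depth=recipient_depth,
        n_reps=n_reps,
        seed=seed if isinstance(seed, int) else None,
        mixture_probs=probs,
        lai_distribution=lai_values,
        asv_ids=universe if as_series else None,
    )


def lai_deviation(observed_lai: LaiRecord | float, expectation: NeutralExpectation) -> float:
    """Observed minus expected LAI: the test statistic for native advantage.

    Accepts either a bare LAI value or a :class:`LaiRecord`; a record whose
    metric differs from the expectation's is an error (the two sides of the
    deviation must use the same similarity measure).
    """
    if isinstance(observed_lai, LaiRecord):
        if observed_lai.metric != expectation.metric:
            raise ValueError(
                f"metric mismatch: observed {observed_lai.metric!r} vs expected {expectation.metric!r}"
            )
        observed = observed_lai.lai
    else:
        observed = float(observed_lai)
    return observed - expectation.expected_lai
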