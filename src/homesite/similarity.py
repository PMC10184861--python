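"""Community similarity measures and the Local Adaptation Index (LAI).

The LAI of a recipient community A competed between two donors is

    LAI(A) = sim(A, donor_native) - sim(A, donor_nonnative)

with ``sim`` either the Jaccard similarity of presence/absence sets
(unweighted) or the Bray-Curtis similarity of relative-abundance vectors
(weighted). LAI lies in [-1, 1]; positive values mean the recipient
resembles its native donor more than its non-native donor — the signature
of home-site advantage for the native community.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LaiRecord",
    "jaccard_similarity",
    "bray_curtis_similarity",
    "lai",
    "lai_filtered",
    "source_log_ratio",
]

METRICS = ("jaccard", "bray_curtis")


@dataclass(frozen=True)
class LaiRecord:
    """Observed LAI of one recipient sample against its two donors."""

    recipient_sample_id: str | None
    metric: str
    sim_native: float
    sim_nonnative: float
    lai: float

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if abs(self.lai - (self.sim_native - self.sim_nonnative)) > 1e-9:
            raise ValueError("lai must equal sim_native - sim_nonnative")


def _as_presence(profile, detection_min: int = 1) -> np.ndarray | frozenset:
    """Coerce a profile (set, boolean array, or count/abundance vector) to a presence representation."""
    if isinstance(profile, (set, frozenset)):
        return frozenset(profile)
    arr = np.asarray(profile)
    if arr.dtype == bool:
        return arr
    return arr >= detection_min if np.issubdtype(arr.dtype, np.integer) else arr > 0


def jaccard_similarity(a, b, detection_min: int = 1) -> float:
    """Jaccard similarity |a n b| / |a u b| of two presence sets.

    ``a`` and ``b`` may be sets of ASV ids, boolean presence vectors on a
    common universe, or count vectors (presence = count >= ``detection_min``;
    non-integer abundance vectors use > 0). Two empty sets are a degenerate
    case and return 1.0 with a warning rather than NaN.
    """
    pa, pb = _as_presence(a, detection_min), _as_presence(b, detection_min)
    if isinstance(pa, frozenset) != isinstance(pb, frozenset):
        raise TypeError("mixed set and vector inputs; pass both as sets or both as vectors")
    if isinstance(pa, frozenset):
        union = len(pa | pb)
        inter = len(pa & pb)
    else:
        if pa.shape != pb.shape:
            raise ValueError(f"presence vectors differ in length: {pa.shape} vs {pb.shape}")
        union = int(np.sum(pa | pb))
        inter = int(np.sum(pa & pb))
    if union == 0:
        warnings.warn("Jaccard of two empty sets is degenerate; returning 1.0", stacklevel=2)
        return 1.0
    return inter / union


def _normalise(v: np.ndarray, label: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if (v < 0).any() or not np.isfinite(v).all():
        raise ValueError(f"{label}: abundances must be finite and non-negative")
    total = v.sum()
    if total == 0:
        raise ValueError(f"{label}: all-zero abundance vector")
    return v / total


def bray_curtis_similarity(a, b) -> float:
    """Bray-Curtis similarity of two abundance vectors on a common universe.

    Inputs may be raw counts or relative abundances; each vector is
    normalised to sum to 1, after which the similarity is
    ``sum_i min(a_i, b_i)`` (one minus the Bray-Curtis dissimilarity).
    """
    va = _normalise(a, "first vector")
    vb = _normalise(b, "second vector")
    if va.shape != vb.shape:
        raise ValueError(f"abundance vectors differ in length: {va.shape} vs {vb.shape}")
    return float(np.minimum(va, vb).sum())


def _align_profiles(*profiles):
    """Align profiles onto a shared ASV universe.

    All-pandas inputs are aligned on the union of their indices (absent ASVs
    filled with 0); array inputs must already share one length.
    """
    if all(isinstance(p, pd.Series) for p in profiles):
        universe = profiles[0].index
        for p in profiles[1:]:
            universe = universe.union(p.index)
        return [p.reindex(universe, fill_value=0).to_numpy(dtype=float) for p in profiles], list(universe)
    arrays = [np.asarray(p, dtype=float) for p in profiles]
    lengths = {a.shape[0] for a in arrays}
    if len(lengths) != 1:
        raise ValueError("array profiles must share one ASV universe (equal lengths)")
    return arrays, None


def _similarity(recipient: np.ndarray, donor: np.ndarray, metric: str, detection_min: int) -> float:
    if metric == "jaccard":
        return jaccard_similarity(recipient, donor, detection_min=detection_min)
    if metric == "bray_curtis":
        return bray_curtis_similarity(recipient, donor)
    raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")


def lai(
    recipient,
    native_donor,
    nonnative_donor,
    metric: str = "jaccard",
    detection_min: int = 1,
    recipient_sample_id: str | None = None,
) -> LaiRecord:
    """Local Adaptation Index of a recipient profile against its two donors.

    Profiles are count or relative-abundance vectors on a shared ASV
    universe (pandas Series are aligned on the union of their indices). For
    the Jaccard metric, presence means count >= ``detection_min``.

    Raises
    ------
    ValueError
        If the recipient profile is empty after the presence rule.
    """
    (rec, nat, non), _ = _align_profiles(recipient, native_donor, nonnative_donor)
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if not np.any(_as_presence(rec, detection_min)):
        raise ValueError("recipient profile is empty after the presence rule")
    sim_nat = _similarity(rec, nat, metric, detection_min)
    sim_non = _similarity(rec, non, metric, detection_min)
    return LaiRecord(recipient_sample_id, metric, sim_nat, sim_non, sim_nat - sim_non)


def lai_filtered(
    recipient: pd.Series,
    native_donor: pd.Series,
    nonnative_donor: pd.Series,
    asv_subset: Sequence[str],
    metric: str = "jaccard",
    detection_min: int = 1,
    recipient_sample_id: str | None = None,
) -> LaiRecord:
    """LAI recomputed on a restricted ASV subset.

    All three profiles are sliced to ``asv_subset`` (intersected with the
    shared universe) before the similarity computations — e.g. the subset of
    ASVs consistently differentially abundant between donor classes. With
    the full universe as subset this equals :func:`lai` exactly.
    """
    (rec, nat, non), universe = _align_profiles(recipient, native_donor, nonnative_donor)
    if universe is None:
        raise TypeError("lai_filtered needs pandas Series profiles with ASV-id indices")
    keep = [a for a in universe if a in set(asv_subset)]
    if not keep:
        raise ValueError("ASV subset is empty after intersection with the profile universe")
    idx = pd.Index(universe).get_indexer(keep)
    return lai(
        pd.Series(rec[idx], index=keep),
        pd.Series(nat[idx], index=keep),
        pd.Series(non[idx], index=keep),
        metric=metric,
        detection_min=detection_min,
        recipient_sample_id=recipient_sample_id,
    )


def source_log_ratio(native_fraction: float, nonnative_fraction: float, epsilon: float = 1e-6) -> float:
    """log10 ratio of native to non-native source fractions.

    ``native_fraction`` and ``nonnative_fraction`` are the fractions of a
    recipient community attributed to each donor by an external source-
    attribution method; the remainder (if any) is "unknown". ``epsilon``
    guards against division by zero when one fraction is exactly 0.
    """
    if native_fraction < 0 or nonnative_fraction < 0:
        raise ValueError("source fractions must be non-negative")
    if native_fraction + nonnative_fraction > 1 + 1e-9:
        raise ValueError("source fractions sum to more than 1")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    num, den = native_fraction + epsilon, nonnative_fraction + epsilon
    if den == 0:
        raise ValueError("non-native fraction is 0 and epsilon is 0: ratio undefined")
    return float(np.log10(num / den))


# ---------------------------------------------------------------------------
# vectorised batch forms (used by the neutral model's Monte-Carlo loop)


def batch_lai(
    counts: np.ndarray,
    native_profile: np.ndarray,
    nonnative_profile: np.ndarray,
    metric: str = "jaccard",
) -> np.ndarray:
    """LAI of each row of an (n_samples, n_asvs) count matrix against two donors.

    Vectorised equivalent of calling :func:`lai` per row; donors are given
    as abundance vectors on the same ASV universe (columns).
    """
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D (samples x ASVs) array")
    if metric == "jaccard":
        present = counts > 0
        d_nat = np.asarray(native_profile) > 0
        d_non = np.asarray(nonnative_profile) > 0
        sim_nat = _batch_jaccard(present, d_nat)
        sim_non = _batch_jaccard(present, d_non)
    elif metric == "bray_curtis":
        totals = counts.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise ValueError("all-zero sample row in counts")
        rel = counts / totals
        sim_nat = _batch_bray_curtis(rel, _normalise(native_profile, "native profile"))
        sim_non = _batch_bray_curtis(rel, _normalise(nonnative_profile, "non-native profile"))
    else:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    return sim_nat - sim_non


def _batch_jaccard(present: np.ndarray, donor_present: np.ndarray) -> np.ndarray:
    inter = present @ donor_present.astype(np.int64)
    union = present.sum(axis=1) + int(donor_present.sum()) - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return sim


def _batch_bray_curtis(rel: np.ndarray, donor_rel: np.ndarray) -> np.ndarray:
    return np.minimum(rel, donor_rel[None, :]).sum(axis=1)
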