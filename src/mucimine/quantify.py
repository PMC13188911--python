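"""Coverage-weighted, length-normalized abundance of profile-HMM families.

The central statistic links three measurements:

* ``N_ij`` — number of significant hits of HMM family *j* among the predicted
  proteins of MAG *i* (genome-intrinsic: MAGs are dereplicated species
  representatives, so the hit count does not vary by sample);
* ``RA_ij = N_ij / (L_j * G_i)`` — hit density per kilo-match-state of
  profile (``L_j``, kb) and per megabase of genome (``G_i``, Mb);
* ``H_ijk = A_ik * RA_ij`` — the density weighted by the mean sequencing
  coverage depth ``A_ik`` of MAG *i* in sample *k*, i.e. how much of family
  *j* that organism contributes to sample *k*;
* ``T_jk = sum_i H_ijk`` — the per-sample family abundance, the matrix every
  downstream screen operates on.

All sample specificity enters through coverage; hit counts are computed once
per MAG. Hits are counted per distinct protein by default so multi-domain
proteins are not inflated (a per-domain mode exists behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import HmmHitRecord, ValidationError

__all__ = [
    "HmmProfileInfo",
    "MagRecord",
    "NormalizedHits",
    "ContributionTable",
    "build_hit_matrix",
    "relative_abundance",
    "normalized_hits",
    "hmm_sample_abundance",
    "mag_contributions",
]

SEED_FAMILIES = (
    "BT4244", "Amuc0627", "Amuc0908", "Amuc1514", "ZmpB", "ZmpC",
    "IMPa", "CpaA", "Pic", "OgpA", "StcE",
)


@dataclass(frozen=True)
class HmmProfileInfo:
    """A profile HMM: its id, length in kilo-match-states, optional seed family."""

    hmm_id: str
    length_kb: float
    seed_family: str | None = None

    def __post_init__(self) -> None:
        if self.length_kb <= 0:
            raise ValidationError(f"profile {self.hmm_id}: length_kb must be > 0")


@dataclass(frozen=True)
class MagRecord:
    """A dereplicated MAG: its id, genome length in Mb, genus label."""

    mag_id: str
    genome_length_mb: float
    genus: str = ""

    def __post_init__(self) -> None:
        if self.genome_length_mb <= 0:
            raise ValidationError(f"MAG {self.mag_id}: genome_length_mb must be > 0")


@dataclass
class NormalizedHits:
    """Dense MAG x HMM x sample tensor of coverage-weighted hit densities."""

    values: np.ndarray  # shape (n_mags, n_hmms, n_samples)
    mags: list[str]
    hmms: list[str]
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mags), len(self.hmms), len(self.samples)):
            raise ValueError("tensor shape does not match label lengths")

    def subset_hmms(self, hmm_ids: Sequence[str]) -> "NormalizedHits":
        idx = [self.hmms.index(h) for h in hmm_ids]
        return NormalizedHits(
            self.values[:, idx, :], list(self.mags), list(hmm_ids), list(self.samples)
        )


@dataclass
class ContributionTable:
    """Per-MAG contribution fractions to each HMM family.

    ``values`` has shape (n_mags, n_hmms) in pooled count mode or
    (n_mags, n_hmms, n_samples) in per-sample modes. ``defined`` marks the
    (hmm,) or (hmm, sample) cells whose denominator was positive; undefined
    cells hold 0, never NaN.
    """

    values: np.ndarray
    mags: list[str]
    hmms: list[str]
    samples: list[str] | None
    defined: np.ndarray
    mode: str


def build_hit_matrix(
    hits: Iterable[HmmHitRecord],
    count_mode: Literal["per_protein", "per_domain"] = "per_protein",
) -> pd.DataFrame:
    """Tally significant hits into an integer MAG x HMM count matrix.

    ``per_protein`` counts each distinct target protein once per HMM even if
    several of its domains match; ``per_domain`` counts every record.
    """
    if count_mode not in ("per_protein", "per_domain"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    seen: set[tuple[str, str, str]] = set()
    counts: dict[tuple[str, str], int] = {}
    mags: list[str] = []
    hmms: list[str] = []
    for h in hits:
        if count_mode == "per_protein":
            key = (h.mag_id, h.hmm_id, h.target_id)
            if key in seen:
                continue
            seen.add(key)
        pair = (h.mag_id, h.hmm_id)
        counts[pair] = counts.get(pair, 0) + 1
        if h.mag_id not in mags:
            mags.append(h.mag_id)
        if h.hmm_id not in hmms:
            hmms.append(h.hmm_id)
    N = pd.DataFrame(0, index=mags, columns=hmms, dtype=int)
    for (mag, hmm), n in counts.items():
        N.loc[mag, hmm] = n
    N.index.name = "mag_id"
    N.columns.name = "hmm_id"
    return N


def _length_maps(
    profiles: Iterable[HmmProfileInfo] | Mapping[str, float],
    mags: Iterable[MagRecord] | Mapping[str, float],
) -> tuple[dict[str, float], dict[str, float]]:
    if isinstance(profiles, Mapping):
        L = dict(profiles)
    else:
        L = {p.hmm_id: p.length_kb for p in profiles}
    if isinstance(mags, Mapping):
        G = dict(mags)
    else:
        G = {m.mag_id: m.genome_length_mb for m in mags}
    return L, G


def relative_abundance(
    N: pd.DataFrame,
    profiles: Iterable[HmmProfileInfo] | Mapping[str, float],
    mags: Iterable[MagRecord] | Mapping[str, float],
) -> pd.DataFrame:
    """RA_ij = N_ij / (L_j * G_i): hit density per profile-kb per genome-Mb."""
    L, G = _length_maps(profiles, mags)
    missing_h = [h for h in N.columns if h not in L]
    if missing_h:
        raise KeyError(f"no profile length for HMM(s): {missing_h}")
    missing_m = [m for m in N.index if m not in G]
    if missing_m:
        raise KeyError(f"no genome length for MAG(s): {missing_m}")
    Lvec = np.array([L[h] for h in N.columns], dtype=float)
    Gvec = np.array([G[m] for m in N.index], dtype=float)
    RA = N.astype(float).values / (Lvec[None, :] * Gvec[:, None])
    return pd.DataFrame(RA, index=N.index.copy(), columns=N.columns.copy())


def normalized_hits(RA: pd.DataFrame, A: pd.DataFrame) -> NormalizedHits:
    """H_ijk = A_ik * RA_ij; every MAG carrying hits must appear in coverage.

    A MAG present in ``RA`` but absent from ``A`` is an error, not a silent
    zero: a genome we found hits in must have a (possibly zero) depth in every
    sample.
    """
    missing = [m for m in RA.index if m not in A.index]
    if missing:
        raise KeyError(f"MAG(s) in hit matrix but not in coverage: {missing}")
    A_sub = A.loc[RA.index]
    if (A_sub.values < 0).any():
        raise ValidationError("negative coverage depth")
    H = A_sub.values[:, None, :] * RA.values[:, :, None]
    return NormalizedHits(
        H,
        mags=[str(m) for m in RA.index],
        hmms=[str(h) for h in RA.columns],
        samples=[str(s) for s in A.columns],
    )


def hmm_sample_abundance(
    H: NormalizedHits,
    depth_rescale: Literal["none", "total_coverage"] = "none",
    coverage: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """T_jk = sum_i H_ijk — the HMM x sample abundance matrix.

    ``depth_rescale="total_coverage"`` additionally divides each sample's
    column by its total MAG coverage (sum_i A_ik), an optional guard against
    residual sequencing-depth differences between samples; samples with zero
    total coverage are left at zero.
    """
    if not np.isfinite(H.values).all():
        raise ValidationError("non-finite entries in normalized hit tensor")
    T = H.values.sum(axis=0)
    if depth_rescale == "total_coverage":
        if coverage is None:
            raise ValueError("total_coverage rescaling requires the coverage matrix")
        totals = coverage.loc[:, H.samples].sum(axis=0).to_numpy(dtype=float)
        T = np.divide(T, totals[None, :], out=np.zeros_like(T),
                      where=totals[None, :] > 0)
    elif depth_rescale != "none":
        raise ValueError(f"unknown depth_rescale mode {depth_rescale!r}")
    out = pd.DataFrame(T, index=pd.Index(H.hmms, name="hmm_id"),
                       columns=pd.Index(H.samples, name="sample_id"))
    return out


def mag_contributions(
    N: pd.DataFrame | None = None,
    A: pd.DataFrame | None = None,
    H: NormalizedHits | None = None,
    mode: Literal["count", "coverage_weighted"] = "count",
) -> ContributionTable:
    """Fraction of each HMM family attributable to each MAG.

    ``count`` mode divides hit counts by the total hits of the family; with a
    coverage table the denominator is restricted, per sample, to MAGs actually
    detected there (A_ik > 0). ``coverage_weighted`` mode uses
    C_ijk = H_ijk / T_jk, the share of sample abundance, which is what group
    level source summaries aggregate.

    Cells whose denominator is zero are flagged undefined and set to 0.
    """
    if mode == "count":
        if N is None:
            raise ValueError("count mode requires the hit matrix N")
        Nv = N.values.astype(float)
        if A is None:
            denom = Nv.sum(axis=0)  # per hmm
            defined = denom > 0
            C = np.divide(Nv, denom[None, :], out=np.zeros_like(Nv),
                          where=denom[None, :] > 0)
            return ContributionTable(C, list(map(str, N.index)),
                                     list(map(str, N.columns)), None, defined, mode)
        missing = [m for m in N.index if m not in A.index]
        if missing:
            raise KeyError(f"MAG(s) missing from coverage: {missing}")
        present = (A.loc[N.index].values > 0)  # mag x sample
        # mag x hmm x sample counts, zeroed where the MAG is absent
        Nv3 = Nv[:, :, None] * present[:, None, :]
        denom = Nv3.sum(axis=0)  # hmm x sample
        defined = denom > 0
        C = np.divide(Nv3, denom[None, :, :], out=np.zeros_like(Nv3),
                      where=denom[None, :, :] > 0)
        return ContributionTable(C, list(map(str, N.index)),
                                 list(map(str, N.columns)),
                                 [str(s) for s in A.columns], defined, mode)
    elif mode == "coverage_weighted":
        if H is None:
            raise ValueError("coverage_weighted mode requires the H tensor")
        T = H.values.sum(axis=0)  # hmm x sample
        defined = T > 0
        C = np.divide(H.values, T[None, :, :], out=np.zeros_like(H.values),
                      where=T[None, :, :] > 0)
        return ContributionTable(C, list(H.mags), list(H.hmms),
                                 list(H.samples), defined, mode)
    raise ValueError(f"unknown contribution mode {mode!r}")
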