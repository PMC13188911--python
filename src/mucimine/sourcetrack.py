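"""Attribute enzyme-family abundance to its producer taxa.

Aggregates the coverage-weighted hit tensor H (MAG x HMM x sample) to
genus-level producer profiles per host-status group: which genera account
for how much of a family's (or a family set's) abundance in cases vs
controls. Coverage weighting is used, not raw hit counts, because a group
summary reflects how abundant the producers actually are in the samples.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import TaxonomyRecord
from .quantify import NormalizedHits

__all__ = ["genus_contributions", "group_source_summary"]

UNASSIGNED = "unassigned"


def _genus_map(taxonomy: Iterable[TaxonomyRecord] | Mapping[str, str]) -> dict[str, str]:
    if isinstance(taxonomy, Mapping):
        raw = dict(taxonomy)
    else:
        raw = {t.mag_id: t.genus for t in taxonomy}
    return {m: (g if g else UNASSIGNED) for m, g in raw.items()}


def genus_contributions(
    H: NormalizedHits,
    taxonomy: Iterable[TaxonomyRecord] | Mapping[str, str],
    group_map: Mapping[str, str],
    hmm_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-group genus shares of the aggregate abundance of an HMM set.

    For each group g: fraction(genus) =
    sum_{i in genus, j in subset, k in g} H_ijk / sum_{i, j in subset, k in g}.
    MAGs without a genus rank pool under ``"unassigned"``. Returns a long
    frame (group, genus, fraction, abundance) sorted by group then descending
    fraction (ties alphabetical). A group whose denominator is zero is
    reported with an empty profile (no rows) — callers can detect it via the
    ``attrs["empty_groups"]`` list.
    """
    genus_of = _genus_map(taxonomy)
    missing = [m for m in H.mags if m not in genus_of]
    if missing:
        raise KeyError(f"MAG(s) without taxonomy record: {missing}")
    if hmm_subset is None:
        sub = H
    else:
        unknown = [h for h in hmm_subset if h not in H.hmms]
        if unknown:
            raise KeyError(f"HMM(s) not in tensor: {unknown}")
        sub = H.subset_hmms(list(hmm_subset))

    groups = np.array([group_map[s] for s in sub.samples])
    genera = np.array([genus_of[m] for m in sub.mags])
    rows = []
    empty_groups = []
    for g in sorted(set(groups)):
        mask = groups == g
        per_mag = sub.values[:, :, mask].sum(axis=(1, 2))  # abundance per MAG
        total = per_mag.sum()
        if total <= 0:
            empty_groups.append(g)
            continue
        series = pd.Series(per_mag).groupby(genera).sum()
        for genus, abundance in series.items():
            rows.append((g, genus, abundance / total, abundance))
    out = pd.DataFrame(rows, columns=["group", "genus", "fraction", "abundance"])
    out = out.sort_values(
        ["group", "fraction", "genus"], ascending=[True, False, True],
        kind="mergesort").reset_index(drop=True)
    out.attrs["empty_groups"] = empty_groups
    return out


def group_source_summary(contrib: pd.DataFrame, top_n: int = 4) -> pd.DataFrame:
    """Top producer genera per group with the remainder pooled as "others".

    Input is the long frame from :func:`genus_contributions`. Per group the
    ``top_n`` genera by fraction are kept (ties broken alphabetically); the
    rest collapse into one "others" row. When a group has no more than
    ``top_n`` genera no "others" row is emitted.
    """
    rows = []
    for g, sub in contrib.groupby("group", sort=True):
        ranked = sub.sort_values(
            ["fraction", "genus"], ascending=[False, True], kind="mergesort")
        head = ranked.head(top_n)
        rows.extend(head[["group", "genus", "fraction", "abundance"]].itertuples(
            index=False, name=None))
        tail = ranked.iloc[top_n:]
        if len(tail):
            rows.append((g, "others", tail["fraction"].sum(),
                         tail["abundance"].sum()))
    return pd.DataFrame(rows, columns=["group", "genus", "fraction", "abundance"])
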