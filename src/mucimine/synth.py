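"""Synthetic cohort generator with planted ground truth.

Emulates the structure of a two-group (case/control) shotgun-metagenome
cohort after assembly, binning and dereplication: a sparse MAG x HMM hit
matrix, a zero-inflated lognormal MAG x sample coverage matrix, GTDB-style
genus labels, and a set of planted group-enriched HMM families whose
producer MAGs are more abundant in cases. Defaults mirror the study design
the pipeline targets: 80 case and 86 control subjects, a few hundred
families of which a tenth are enriched two-fold in cases.

Planted differential families receive *dedicated* producer MAGs — MAGs that
carry hits only for their assigned family, while background MAGs carry hits
only on null families. This keeps the planted effect from leaking into null
families through shared producers, so sensitivity/FDR of the screen are
well-defined against the truth. The ground-truth genus fractions are the
analytic expectations under the generative model (not recomputed from the
realized matrices), so comparing them with the source-tracking output is a
genuine estimation check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    HmmHitRecord,
    SampleMetadata,
    TaxonomyRecord,
    write_hmm_hits,
    write_mag_table,
    write_matrix,
    write_metadata,
    write_profile_table,
    write_taxonomy,
)
from .quantify import HmmProfileInfo, MagRecord

__all__ = ["SimulationConfig", "GroundTruth", "SimulatedDataset",
           "simulate_dataset", "write_dataset"]

DEFAULT_GENUS_POOL = (
    "Bacteroides", "Phocaeicola", "Akkermansia", "Alistipes", "Escherichia",
    "Prevotella", "Parabacteroides", "Streptococcus", "Gemmiger",
    "Lawsonibacter",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults are the emulated study's conditions.

    ``coverage_dispersion`` is the sigma of the per-sample lognormal coverage
    noise around each MAG's characteristic depth; ``zero_inflation`` the
    probability a MAG is absent from a sample; ``hit_density`` the expected
    fraction of background (MAG, family) pairs with any hits;
    ``producers_per_differential`` the number of dedicated producer MAGs each
    planted family receives.
    """

    n_case: int = 80
    n_control: int = 86
    n_mags: int = 120
    n_hmms: int = 300
    n_differential: int = 30
    effect_size: float = 2.0
    genus_pool: tuple[str, ...] = DEFAULT_GENUS_POOL
    hit_density: float = 0.05
    coverage_dispersion: float = 0.5
    zero_inflation: float = 0.2
    producers_per_differential: int = 3
    hit_count_geom_p: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_case, self.n_control, self.n_mags, self.n_hmms) < 1:
            raise ValueError("sample/MAG/HMM counts must be >= 1")
        if not 0 <= self.n_differential <= self.n_hmms:
            raise ValueError("n_differential must lie in [0, n_hmms]")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if not (0 <= self.hit_density <= 1 and 0 <= self.zero_inflation <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        need = self.n_differential * self.producers_per_differential
        if need >= self.n_mags:
            raise ValueError(
                f"need {need} dedicated producer MAGs but only "
                f"{self.n_mags} MAGs configured")


@dataclass
class GroundTruth:
    """What was planted: differential families, their producers, genus shares."""

    differential_hmm_ids: list[str]
    producers: dict[str, list[str]]  # hmm_id -> dedicated producer MAG ids
    genus_fractions: dict[str, dict[str, float]]  # group -> genus -> expected share

    def to_json(self) -> str:
        return json.dumps(
            {
                "differential_hmm_ids": self.differential_hmm_ids,
                "producers": self.producers,
                "genus_fractions": self.genus_fractions,
            },
            indent=2, sort_keys=True)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    mags: list[MagRecord]
    profiles: list[HmmProfileInfo]
    hits: list[HmmHitRecord]
    hit_matrix: pd.DataFrame  # MAG x HMM integer counts
    coverage: pd.DataFrame  # MAG x sample
    metadata: list[SampleMetadata]
    taxonomy: list[TaxonomyRecord]
    truth: GroundTruth


def _lineage(genus: str, domain: str = "Bacteria") -> str:
    if not genus:
        return f"d__{domain};p__;c__;o__;f__;g__;s__"
    return (f"d__{domain};p__P_{genus};c__C_{genus};o__O_{genus};"
            f"f__F_{genus};g__{genus};s__{genus} sp.")


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw a full cohort with planted group-enriched families.

    Generative model: genome lengths ~ U(1, 8) Mb; profile lengths
    ~ U(300, 1500) match states; background hit presence ~ Bernoulli(
    hit_density) with counts 1 + geometric tail; per-MAG characteristic
    log-depth mu_i ~ N(0.5, 1); coverage A_ik = Bernoulli(1 - zero_inflation)
    x LogNormal(mu_i, coverage_dispersion), multiplied by ``effect_size`` in
    case samples for the dedicated producers of differential families.
    Bit-reproducible given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    mag_ids = [f"MAG{i + 1:04d}" for i in range(cfg.n_mags)]
    hmm_ids = [f"HMM{j + 1:04d}" for j in range(cfg.n_hmms)]
    sample_ids = [f"S{k + 1:04d}" for k in range(cfg.n_case + cfg.n_control)]
    groups = ["case"] * cfg.n_case + ["control"] * cfg.n_control

    genome_mb = rng.uniform(1.0, 8.0, cfg.n_mags)
    match_states = rng.integers(300, 1501, cfg.n_hmms)
    # genus skew: geometric weights over the pool (front-loaded dominance)
    weights = 0.65 ** np.arange(len(cfg.genus_pool))
    weights /= weights.sum()
    genus_idx = rng.choice(len(cfg.genus_pool), cfg.n_mags, p=weights)
    genera = [cfg.genus_pool[i] for i in genus_idx]

    # planted families and their dedicated producers
    diff_idx = sorted(rng.choice(cfg.n_hmms, cfg.n_differential, replace=False))
    n_dedicated = cfg.n_differential * cfg.producers_per_differential
    dedicated_idx = rng.choice(cfg.n_mags, n_dedicated, replace=False)
    producers: dict[str, list[str]] = {}
    producer_of_mag = np.full(cfg.n_mags, -1)  # hmm index or -1
    for d, j in enumerate(diff_idx):
        block = dedicated_idx[d * cfg.producers_per_differential:
                              (d + 1) * cfg.producers_per_differential]
        producers[hmm_ids[j]] = [mag_ids[i] for i in block]
        producer_of_mag[block] = j
    is_dedicated = producer_of_mag >= 0
    is_diff = np.zeros(cfg.n_hmms, dtype=bool)
    is_diff[diff_idx] = True

    # hit matrix: background MAGs on null families; dedicated MAGs only on theirs
    N = np.zeros((cfg.n_mags, cfg.n_hmms), dtype=int)
    present = rng.random((cfg.n_mags, cfg.n_hmms)) < cfg.hit_density
    present[:, is_diff] = False
    present[is_dedicated, :] = False
    counts = rng.geometric(cfg.hit_count_geom_p, size=present.shape)
    N[present] = counts[present]
    for i in np.flatnonzero(is_dedicated):
        N[i, producer_of_mag[i]] = rng.geometric(cfg.hit_count_geom_p)

    # coverage: zero-inflated lognormal around a per-MAG characteristic depth
    mu = rng.normal(0.5, 1.0, cfg.n_mags)
    n_samples = len(sample_ids)
    detected = rng.random((cfg.n_mags, n_samples)) >= cfg.zero_inflation
    depth = rng.lognormal(mean=mu[:, None], sigma=cfg.coverage_dispersion,
                          size=(cfg.n_mags, n_samples))
    A = np.where(detected, depth, 0.0)
    case_cols = np.array([g == "case" for g in groups])
    boost = np.ones((cfg.n_mags, n_samples))
    boost[np.ix_(is_dedicated, case_cols)] = cfg.effect_size
    A *= boost

    # expected genus fractions over the differential subset, per group:
    # only dedicated producers contribute; E[A_ik] = (1-zi) * exp(mu+s^2/2) * boost
    expected_depth = (1 - cfg.zero_inflation) * np.exp(
        mu + cfg.coverage_dispersion**2 / 2)
    genus_fractions: dict[str, dict[str, float]] = {}
    for group, factor in (("case", cfg.effect_size), ("control", 1.0)):
        contrib: dict[str, float] = {}
        for i in np.flatnonzero(is_dedicated):
            j = producer_of_mag[i]
            ra = N[i, j] / ((match_states[j] / 1000.0) * genome_mb[i])
            val = expected_depth[i] * factor * ra
            contrib[genera[i]] = contrib.get(genera[i], 0.0) + val
        total = sum(contrib.values())
        genus_fractions[group] = (
            {g: float(v / total) for g, v in sorted(contrib.items())}
            if total > 0 else {})

    # hit records with synthetic E-values well under threshold, plus decoys above
    hits: list[HmmHitRecord] = []
    for i, mag in enumerate(mag_ids):
        for j, hmm in enumerate(hmm_ids):
            for c in range(N[i, j]):
                ev = 10.0 ** rng.uniform(-30, -6)
                hits.append(HmmHitRecord(
                    target_id=f"{mag}~P{j + 1:04d}_{c + 1}",
                    mag_id=mag, hmm_id=hmm,
                    full_seq_evalue=float(ev),
                    full_seq_score=float(rng.uniform(50, 500))))
    n_decoys = max(1, int(0.05 * len(hits)))
    for d in range(n_decoys):
        i = int(rng.integers(cfg.n_mags))
        j = int(rng.integers(cfg.n_hmms))
        hits.append(HmmHitRecord(
            target_id=f"{mag_ids[i]}~DECOY{d + 1:04d}",
            mag_id=mag_ids[i], hmm_id=hmm_ids[j],
            full_seq_evalue=float(10.0 ** rng.uniform(-4, 0)),
            full_seq_score=float(rng.uniform(5, 20))))

    mags = [MagRecord(m, float(genome_mb[i]), genera[i])
            for i, m in enumerate(mag_ids)]
    profiles = [HmmProfileInfo(h, float(match_states[j]) / 1000.0)
                for j, h in enumerate(hmm_ids)]
    hit_matrix = pd.DataFrame(N, index=pd.Index(mag_ids, name="mag_id"),
                              columns=pd.Index(hmm_ids, name="hmm_id"))
    coverage = pd.DataFrame(A, index=pd.Index(mag_ids, name="Genome"),
                            columns=pd.Index(sample_ids, name="sample_id"))
    metadata = [SampleMetadata(s, g) for s, g in zip(sample_ids, groups)]
    taxonomy = [TaxonomyRecord(m, _lineage(genera[i]), genera[i])
                for i, m in enumerate(mag_ids)]
    truth = GroundTruth(
        differential_hmm_ids=[hmm_ids[j] for j in diff_idx],
        producers=producers,
        genus_fractions=genus_fractions)
    return SimulatedDataset(cfg, mags, profiles, hits, hit_matrix, coverage,
                            metadata, taxonomy, truth)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a dataset in the on-disk formats the readers consume.

    Produces hits.tbl (hmmsearch --tblout layout, decoys included so the
    E-value filter is exercised), coverage.tsv, taxonomy.tsv, metadata.tsv,
    profiles.tsv, mags.tsv and truth.json under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hits": outdir / "hits.tbl",
        "coverage": outdir / "coverage.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "metadata": outdir / "metadata.tsv",
        "profiles": outdir / "profiles.tsv",
        "mags": outdir / "mags.tsv",
        "truth": outdir / "truth.json",
    }
    write_hmm_hits(ds.hits, paths["hits"])
    write_matrix(ds.coverage, paths["coverage"], index_name="Genome")
    write_taxonomy(ds.taxonomy, paths["taxonomy"])
    write_metadata(ds.metadata, paths["metadata"])
    write_profile_table(ds.profiles, paths["profiles"])
    write_mag_table(ds.mags, paths["mags"])
    paths["truth"].write_text(ds.truth.to_json() + "\n")
    return paths
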