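"""Profile-library preparation: length QC and greedy identity clustering.

Covers the steps of building an enzyme-family HMM library that are worth
owning: selecting proteins in the 300-3000 aa range (inclusive), computing
pairwise global-alignment identity, and CD-HIT-style greedy clustering at a
sequence-identity threshold (default 80%). Multiple alignment and HMM
construction stay with the standard external tools (MAFFT, hmmbuild); this
module only records the exact commands to run them so a library build is
reproducible.

Identity convention: matched columns divided by global alignment length
(match 1 / mismatch 0 / gap -1 scoring, first optimal alignment). CD-HIT
itself divides by the shorter sequence length; that mode is available via
``denominator="shorter"`` and the default is a documented deviation — at an
80% threshold on similar-length proteins the two rarely disagree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinSeq",
    "Cluster",
    "read_fasta",
    "write_fasta",
    "filter_by_length",
    "pairwise_identity",
    "cluster_greedy_identity",
    "write_clusters",
    "mafft_command",
    "hmmbuild_command",
    "write_adapter_config",
]

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinSeq:
    """An amino-acid sequence (canonical uppercase, 20 letters + X)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id}: empty residues")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.id}: invalid residue(s) {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Cluster:
    representative: ProteinSeq
    members: list[tuple[ProteinSeq, float]]  # (member, identity to representative)


def read_fasta(path: str | Path) -> list[ProteinSeq]:
    return [ProteinSeq(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Iterable[ProteinSeq], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def filter_by_length(
    seqs: Iterable[ProteinSeq], min_len: int = 300, max_len: int = 3000
) -> list[ProteinSeq]:
    """Keep sequences with min_len <= length <= max_len (both inclusive)."""
    return [s for s in seqs if min_len <= len(s) <= max_len]


def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(
    a: ProteinSeq,
    b: ProteinSeq,
    denominator: Literal["alignment", "shorter"] = "alignment",
) -> float:
    """Fraction of identical columns between two sequences under global alignment.

    ``alignment`` divides identities by the alignment length (gap columns
    included); ``shorter`` divides by the shorter sequence's length (CD-HIT's
    convention).
    """
    aln = _aligner().align(a.residues, b.residues)[0]
    counts = aln.counts()
    identities = counts.identities
    if denominator == "alignment":
        denom = counts.gaps + counts.identities + counts.mismatches
    elif denominator == "shorter":
        denom = min(len(a), len(b))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return identities / denom


def cluster_greedy_identity(
    seqs: Sequence[ProteinSeq],
    threshold: float = 0.80,
    denominator: Literal["alignment", "shorter"] = "alignment",
) -> list[Cluster]:
    """Greedy incremental clustering at a sequence-identity threshold.

    Sequences are processed longest first (ties broken by id); each joins the
    first existing cluster whose *representative* it matches at >= threshold,
    otherwise it founds a new cluster and becomes its representative. The
    result is deterministic for a given input set.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    ordered = sorted(seqs, key=lambda s: (-len(s), s.id))
    clusters: list[Cluster] = []
    for seq in ordered:
        for cl in clusters:
            ident = pairwise_identity(seq, cl.representative, denominator)
            if ident >= threshold:
                cl.members.append((seq, ident))
                break
        else:
            clusters.append(Cluster(seq, [(seq, 1.0)]))
    return clusters


def write_clusters(clusters: Iterable[Cluster], path: str | Path) -> None:
    """Cluster membership TSV: cluster_id, representative_id, member_id, identity."""
    with open(path, "w") as fh:
        fh.write("cluster_id\trepresentative_id\tmember_id\tidentity\n")
        for i, cl in enumerate(clusters):
            for member, ident in cl.members:
                fh.write(f"C{i:05d}\t{cl.representative.id}\t{member.id}\t"
                         f"{ident:.4f}\n")


def mafft_command(fasta_in: str | Path) -> list[str]:
    """The MAFFT invocation used to align a cluster before HMM construction.

    MAFFT writes the alignment to stdout; redirect it to the .aln file.
    """
    return ["mafft", "--auto", str(fasta_in)]


def hmmbuild_command(hmm_out: str | Path, aln_in: str | Path, name: str) -> list[str]:
    """The hmmbuild invocation turning an alignment into a profile HMM."""
    return ["hmmbuild", "-n", name, str(hmm_out), str(aln_in)]


def write_adapter_config(
    path: str | Path,
    commands: dict[str, list[str]],
) -> None:
    """Record external-tool commands (MAFFT, hmmbuild, ...) for provenance."""
    with open(path, "w") as fh:
        json.dump({"external_commands": commands}, fh, indent=2, sort_keys=True)
        fh.write("\n")
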