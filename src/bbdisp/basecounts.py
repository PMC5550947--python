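"""Base-level read-start count tracks and their local-sequence contexts.

A "track" is the vector of read 5'-start counts along one gene for one
sample on one strand.  Two tracks for the same gene from two samples are
combined into a :class:`PairedCounts` object carrying, per position, the
two counts (n, m), their total (the depth covariate) and the local-sequence
window used by the overdispersion regression.

Coordinates are 0-based, half-open everywhere internally; 1-based only at
text-format boundaries (none of the formats here use 1-based positions).
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("bbdisp")

SENSE = "sense"
ANTISENSE = "antisense"
STRANDS = (SENSE, ANTISENSE)

#: Marker stored in a context array when the window runs off the sequence
#: (or no sequence is available for the gene).
MISSING_CONTEXT = "."

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Malformed input file (bad column, negative count, bad strand...)."""


class ConfigError(ValueError):
    """Inconsistent run configuration (unknown sample, bad parameter...)."""


class AlignmentMismatchError(ValueError):
    """Two tracks that should cover identical positions do not."""


class EstimationError(ValueError):
    """An estimator received data it cannot work with (e.g. zero totals)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One gene/transcript: spliced sequence in transcript orientation.

    ``sequence`` may be None when only the length is known (counts-table
    input without a FASTA); windows are then all missing and only models
    without sequence terms can be fitted.
    """

    gene_id: str
    sequence: str | None = None
    strand: str = SENSE
    length: int = 0

    def __post_init__(self):
        if self.sequence is not None:
            seq = self.sequence.upper()
            object.__setattr__(self, "sequence", seq)
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(f"{self.gene_id}: invalid bases {sorted(bad)}")
            if self.length and self.length != len(seq):
                raise FormatError(f"{self.gene_id}: length {self.length} != sequence length {len(seq)}")
            object.__setattr__(self, "length", len(seq))
        if self.length <= 0:
            raise FormatError(f"{self.gene_id}: non-positive length")
        if self.strand not in STRANDS:
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass
class BaseStartCounts:
    """Read 5'-start counts by 0-based position within one gene/sample/strand."""

    gene_id: str
    sample_id: str
    strand: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise FormatError("counts must be a 1-D vector")
        if (self.counts < 0).any():
            raise FormatError(f"{self.gene_id}/{self.sample_id}: negative count")
        if self.strand not in STRANDS:
            raise FormatError(f"bad strand {self.strand!r}")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class FilterConfig:
    """Positional filters applied before estimation.

    read_length_trim
        Positions removed from the 3' end of the transcript where no
        full-length read can start (set to the read length of the run).
    tail_trim
        Additional 3'-end removal; recommended 200 for protocols in which
        fragment selection follows PCR amplification (inflated tail
        dispersion), 0 otherwise.
    min_depth
        A position enters dispersion estimation only if every replicate
        pair has total depth (n+m) at or above this.
    """

    read_length_trim: int = 0
    tail_trim: int = 0
    min_depth: int = 5

    def __post_init__(self):
        if min(self.read_length_trim, self.tail_trim, self.min_depth) < 0:
            raise ConfigError("filter fields must be >= 0")


@dataclass
class PairedCounts:
    """Position-aligned count vectors for one gene from a sample pair."""

    gene_id: str
    strand: str
    positions: np.ndarray
    n: np.ndarray
    m: np.ndarray
    context: np.ndarray  # unicode array; MISSING_CONTEXT where unavailable

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        self.m = np.asarray(self.m, dtype=np.int64)
        self.context = np.asarray(self.context)
        lens = {len(self.positions), len(self.n), len(self.m), len(self.context)}
        if len(lens) != 1:
            raise AlignmentMismatchError(f"{self.gene_id}: unequal vector lengths {lens}")

    @property
    def depth(self) -> np.ndarray:
        return self.n + self.m

    def __len__(self) -> int:
        return len(self.positions)


# ---------------------------------------------------------------------------
# sequence / context helpers
# ---------------------------------------------------------------------------

def context_windows(sequence: str | None, n_positions: int, K: int) -> np.ndarray:
    """Local-sequence window for each of the first ``n_positions`` positions.

    The window of position j is the K/2 bases before and K/2 bases after j;
    the read-start base itself is excluded.  Positions whose window extends
    past the available sequence get :data:`MISSING_CONTEXT`.
    """
    if K <= 0 or K % 2:
        raise ConfigError("K must be a positive even integer")
    half = K // 2
    out = np.full(n_positions, MISSING_CONTEXT, dtype=f"U{K}")
    if sequence is None:
        return out
    L = len(sequence)
    lo = half
    hi = min(n_positions, L - half - 1)
    for j in range(lo, hi):
        out[j] = sequence[j - half:j] + sequence[j + 1:j + 1 + half]
    return out


def read_fasta(path) -> dict[str, GeneModel]:
    """One GeneModel per FASTA record (spliced transcript sequences)."""
    from Bio import SeqIO

    genes: dict[str, GeneModel] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genes:
            raise FormatError(f"duplicate gene id {rec.id}")
        genes[rec.id] = GeneModel(gene_id=rec.id, sequence=str(rec.seq))
    return genes


def write_fasta(genes: Mapping[str, GeneModel], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genes.values():
            if g.sequence is None:
                raise ConfigError(f"{g.gene_id}: no sequence to write")
            fh.write(f">{g.gene_id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i:i + width] + "\n")


def read_sample_sheet(path) -> dict[str, str]:
    """Tab-separated (sample_id, group[, library_id]) -> {sample_id: group}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample_id", "group"}
    if not need <= set(df.columns):
        raise FormatError(f"sample sheet needs columns {sorted(need)}, got {list(df.columns)}")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in sample sheet")
    return dict(zip(df["sample_id"], df["group"]))


# ---------------------------------------------------------------------------
# counts table I/O
# ---------------------------------------------------------------------------

COUNTS_COLUMNS = ["gene_id", "strand", "position", "sample_id", "count"]


def load_counts_table(path,
                      sample_sheet: Mapping[str, str] | None = None,
                      genes: Mapping[str, GeneModel] | None = None,
                      ) -> dict[tuple[str, str, str], BaseStartCounts]:
    """Read a per-base counts table into dense tracks.

    The file is tab-separated with header columns gene_id, strand, position,
    sample_id, count (positions 0-based, gzip transparent).  Missing
    positions are filled with 0 up to the gene length (taken from ``genes``
    when provided, otherwise from the largest observed position).

    Returns a mapping (gene_id, sample_id, strand) -> BaseStartCounts.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "strand": str,
                                            "sample_id": str})
    if df.empty:
        logger.warning("counts table %s is empty", path)
        return {}
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"counts table missing columns {sorted(missing)}")
    if (df["count"] < 0).any():
        raise FormatError("negative count in counts table")
    if (df["position"] < 0).any():
        raise FormatError("negative position in counts table")
    bad_strand = set(df["strand"].unique()) - set(STRANDS)
    if bad_strand:
        raise FormatError(f"unknown strand value(s) {sorted(bad_strand)}")
    if sample_sheet is not None:
        unknown = set(df["sample_id"].unique()) - set(sample_sheet)
        if unknown:
            raise ConfigError(f"sample id(s) not in sample sheet: {sorted(unknown)}")

    out: dict[tuple[str, str, str], BaseStartCounts] = {}
    for (gid, sid, strand), grp in df.groupby(["gene_id", "sample_id", "strand"], sort=True):
        if genes is not None:
            if gid not in genes:
                logger.warning("gene %s not in reference, skipped", gid)
                continue
            length = genes[gid].length
        else:
            length = int(grp["position"].max()) + 1
        pos = grp["position"].to_numpy()
        if genes is not None and (pos >= length).any():
            raise FormatError(f"{gid}: position beyond gene length {length}")
        counts = np.zeros(length, dtype=np.int64)
        np.add.at(counts, pos, grp["count"].to_numpy())
        out[(gid, sid, strand)] = BaseStartCounts(gid, sid, strand, counts)
    return out


def write_counts_table(tracks: Iterable[BaseStartCounts], path) -> None:
    """Serialize tracks sparsely (non-zero positions only)."""
    rows = []
    for t in tracks:
        nz = np.nonzero(t.counts)[0]
        rows.append(pd.DataFrame({
            "gene_id": t.gene_id, "strand": t.strand, "position": nz,
            "sample_id": t.sample_id, "count": t.counts[nz]}))
    if rows:
        df = pd.concat(rows, ignore_index=True)
    else:
        df = pd.DataFrame(columns=COUNTS_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BAM extraction
# ---------------------------------------------------------------------------

def counts_from_bam(bam_path,
                    genes: Mapping[str, GeneModel],
                    strand_mode: str = "unstranded",
                    min_mapq: int = 30,
                    sample_id: str | None = None,
                    ) -> dict[tuple[str, str, str], BaseStartCounts]:
    """Per-base 5'-start counts from a coordinate-sorted, indexed BAM.

    Alignments are expected in transcript coordinates (one reference per
    gene).  Only primary, uniquely mapped reads count: mapping quality >=
    ``min_mapq`` (default 30; reads an aligner marks multi-mapped get low
    MAPQ).  The counted position is the 5' end of the read on its own
    strand: reference_start for forward alignments, reference_end-1 for
    reverse ones.

    strand_mode
        "unstranded": every read counts toward the sense strand.
        "stranded_mate": dUTP protocol; the second mate carries transcript
        orientation, so read2-forward / read1-reverse count as sense and
        the complementary configurations as antisense.
    """
    import pysam

    if strand_mode not in ("unstranded", "stranded_mate"):
        raise ConfigError(f"unknown strand_mode {strand_mode!r}")
    with pysam.AlignmentFile(str(bam_path)) as bam:
        if not bam.has_index():
            raise OSError(f"{bam_path}: BAM index required")
        if sample_id is None:
            sample_id = str(bam_path).rsplit("/", 1)[-1].removesuffix(".bam")
        acc: dict[tuple[str, str], np.ndarray] = {}
        refs = set(bam.references)
        for gid, gene in genes.items():
            if gid not in refs:
                logger.warning("gene %s absent from BAM header, skipped", gid)
                continue
            for read in bam.fetch(gid):
                if (read.is_unmapped or read.is_secondary or read.is_supplementary
                        or read.is_qcfail or read.is_duplicate):
                    continue
                if read.mapping_quality < min_mapq:
                    continue
                pos = read.reference_end - 1 if read.is_reverse else read.reference_start
                if not 0 <= pos < gene.length:
                    continue
                if strand_mode == "unstranded":
                    strand = SENSE
                else:
                    # dUTP: mate2 carries transcript orientation; single-end
                    # reads are treated as mate1.
                    second = read.is_paired and read.is_read2
                    forward = not read.is_reverse
                    strand = SENSE if (second and forward) or (not second and not forward) \
                        else ANTISENSE
                key = (gid, strand)
                if key not in acc:
                    acc[key] = np.zeros(gene.length, dtype=np.int64)
                acc[key][pos] += 1
    return {(gid, sample_id, strand): BaseStartCounts(gid, sample_id, strand, v)
            for (gid, strand), v in acc.items()}


# ---------------------------------------------------------------------------
# filtering and pairing
# ---------------------------------------------------------------------------

def apply_filters(counts: BaseStartCounts, gene: GeneModel,
                  cfg: FilterConfig) -> BaseStartCounts | None:
    """Trim 3'-end positions (read-length + optional tail trim).

    The returned track covers positions 0 .. L - read_length_trim -
    tail_trim - 1; trimmed positions are removed, not zeroed.  Returns None
    (with a warning) when the trims consume the whole gene.
    """
    keep = gene.length - cfg.read_length_trim - cfg.tail_trim
    if keep <= 0:
        logger.warning("gene %s shorter than trims, excluded", gene.gene_id)
        return None
    return BaseStartCounts(counts.gene_id, counts.sample_id, counts.strand,
                           counts.counts[:keep])


def pair_counts(a: BaseStartCounts, b: BaseStartCounts, gene: GeneModel,
                K: int = 80) -> PairedCounts:
    """Align two tracks of the same gene/strand into a PairedCounts.

    Context windows are taken from the full gene sequence (positions beyond
    the filtered track may still provide window bases).
    """
    if (a.gene_id, a.strand) != (b.gene_id, b.strand):
        raise AlignmentMismatchError(
            f"cannot pair {a.gene_id}/{a.strand} with {b.gene_id}/{b.strand}")
    if len(a.counts) != len(b.counts):
        raise AlignmentMismatchError(
            f"{a.gene_id}: mismatched position sets ({len(a.counts)} vs {len(b.counts)})")
    L = len(a.counts)
    ctx = context_windows(gene.sequence, L, K)
    return PairedCounts(gene_id=a.gene_id, strand=a.strand,
                        positions=np.arange(L), n=a.counts.copy(),
                        m=b.counts.copy(), context=ctx)


def build_pairs(counts: Mapping[tuple[str, str, str], BaseStartCounts],
                genes: Mapping[str, GeneModel],
                sample_a: str, sample_b: str,
                K: int = 80,
                filters: FilterConfig = FilterConfig(),
                ) -> list[PairedCounts]:
    """Filtered, position-aligned PairedCounts for every gene/strand that
    both samples cover."""
    out: list[PairedCounts] = []
    keys_a = {(g, s) for (g, smp, s) in counts if smp == sample_a}
    keys_b = {(g, s) for (g, smp, s) in counts if smp == sample_b}
    for g, s in sorted(keys_a & keys_b):
        if g not in genes:
            logger.warning("gene %s not in reference, skipped", g)
            continue
        fa = apply_filters(counts[(g, sample_a, s)], genes[g], filters)
        fb = apply_filters(counts[(g, sample_b, s)], genes[g], filters)
        if fa is None or fb is None:
            continue
        out.append(pair_counts(fa, fb, genes[g], K=K))
    return out


def replicate_pairs(sample_ids: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered combination pairs of replicates."""
    return list(itertools.combinations(sample_ids, 2))
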