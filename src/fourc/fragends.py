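"""DpnII fragend library construction, read demultiplexing and exact mapping.

4C-seq reads begin with a viewpoint-specific primer and continue into the
captured restriction fragment, so the first bases after the primer identify
the fragment end ("fragend") that was ligated to the viewpoint. Mapping
therefore reduces to an exact lookup of the first 16 payload bases against
an in-silico digest of the genome: every GATC site contributes two fragends
(one on each side of the site), and only fragends whose 16-mer is unique
genome-wide are usable for coverage calling.

Coordinates are 0-based half-open throughout. GATC is palindromic, so sites
are detected on the forward strand only; fragend 16-mers are stored in
forward-genomic orientation, excluding the GATC recognition sequence itself.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ViewpointSpec",
    "FragendLibrary",
    "CoverageProfile",
    "build_fragend_library",
    "demultiplex",
    "map_reads",
    "write_coverage_bed",
    "read_coverage_bed",
]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class ViewpointSpec:
    """One 4C viewpoint: a tag-SNP locus with its inverse-PCR primer."""

    snp_id: str
    chrom: str
    position: int
    primer: str
    cell_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.primer:
            raise ValueError(f"viewpoint {self.snp_id}: primer must be non-empty")
        if self.position < 0:
            raise ValueError(f"viewpoint {self.snp_id}: negative position")


@dataclass
class FragendLibrary:
    """In-silico digest: per-chromosome tables of fragends.

    Each table has columns ``start, end, side, seq, mappable, unique``:
    ``side`` is "up"/"down" relative to the GATC site, ``mappable`` is True
    when the flank has the full 16 bases of unambiguous sequence, ``unique``
    when its 16-mer occurs at exactly one fragend genome-wide.
    """

    chroms: dict[str, pd.DataFrame]
    chrom_lengths: dict[str, int]
    site: str = "GATC"
    flank: int = 16
    _index: dict[str, tuple[str, int]] | None = field(default=None, repr=False)

    def usable(self, chrom: str) -> pd.DataFrame:
        """Fragends that can report coverage: mappable and unique."""
        df = self.chroms[chrom]
        return df[df["mappable"] & df["unique"]].reset_index(drop=True)

    @property
    def seq_index(self) -> dict[str, tuple[str, int]]:
        """16-mer -> (chrom, row within ``usable(chrom)``) for usable fragends."""
        if self._index is None:
            idx: dict[str, tuple[str, int]] = {}
            for chrom in self.chroms:
                for i, s in enumerate(self.usable(chrom)["seq"]):
                    idx[s] = (chrom, i)
            self._index = idx
        return self._index

    def n_fragends(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.chroms[chrom])
        return sum(len(df) for df in self.chroms.values())


@dataclass
class CoverageProfile:
    """Binary covered/uncovered status for the usable fragends of one
    viewpoint chromosome, for one viewpoint in one cell type.

    ``counts`` holds raw read counts (kept for QC); the binary ``status``
    used by all downstream statistics is simply ``counts >= 1``.
    """

    viewpoint: ViewpointSpec
    cell_type: str
    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    counts: np.ndarray
    seqs: tuple[str, ...] | None = None
    trans_counts: dict[str, np.ndarray] | None = None
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if not (len(self.starts) == len(self.ends) == len(self.counts)):
            raise ValueError("coverage arrays must have equal length")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def status(self) -> np.ndarray:
        return (self.counts >= 1).astype(np.int8)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    @property
    def n_covered(self) -> int:
        return int((self.counts >= 1).sum())


def build_fragend_library(
    genome: dict[str, str], site: str = "GATC", flank: int = 16
) -> FragendLibrary:
    """Digest a genome in silico and index the fragends flanking every site.

    Every occurrence of ``site`` on the forward strand yields two fragends:
    the ``flank`` bases ending immediately before the site ("up") and the
    ``flank`` bases starting immediately after it ("down"). A fragend
    truncated by the chromosome end or by an adjacent site, or containing an
    ambiguous base, is flagged non-mappable. Uniqueness of the mapping
    k-mers is computed over all mappable fragends genome-wide.
    """
    per_chrom: dict[str, pd.DataFrame] = {}
    lengths: dict[str, int] = {}
    all_seqs: list[str] = []
    for chrom, seq in genome.items():
        s = str(seq).upper()
        lengths[chrom] = len(s)
        if len(s) < flank:
            warnings.warn(f"{chrom}: shorter than {flank} bp, no fragends")
            per_chrom[chrom] = _empty_table()
            continue
        sites = [m.start() for m in re.finditer(re.escape(site), s)]
        rows = []
        for i, p in enumerate(sites):
            prev_end = sites[i - 1] + len(site) if i > 0 else 0
            next_start = sites[i + 1] if i + 1 < len(sites) else len(s)
            u_start = max(0, p - flank, prev_end)
            u_seq = s[u_start:p]
            rows.append(
                (u_start, p, "up", u_seq, len(u_seq) == flank and _unambiguous(u_seq))
            )
            d_start = p + len(site)
            d_end = min(len(s), d_start + flank, next_start)
            d_seq = s[d_start:d_end]
            rows.append(
                (d_start, d_end, "down", d_seq, len(d_seq) == flank and _unambiguous(d_seq))
            )
        df = pd.DataFrame(rows, columns=["start", "end", "side", "seq", "mappable"])
        per_chrom[chrom] = df.sort_values("start", kind="stable").reset_index(drop=True)
        all_seqs.extend(df.loc[df["mappable"], "seq"])
    counts = pd.Series(all_seqs).value_counts() if all_seqs else pd.Series(dtype=int)
    for chrom, df in per_chrom.items():
        if len(df) == 0:
            continue
        uniq = df["seq"].map(counts).eq(1) & df["mappable"]
        df["unique"] = uniq.to_numpy()
    return FragendLibrary(per_chrom, lengths, site=site, flank=flank)


def _unambiguous(s: str) -> bool:
    return set(s) <= _ACGT


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["start", "end", "side", "seq", "mappable", "unique"]
    ).astype({"start": np.int64, "end": np.int64, "mappable": bool, "unique": bool})


def demultiplex(
    reads, viewpoints: list[ViewpointSpec]
) -> tuple[dict[str, list[str]], int]:
    """Assign reads to viewpoints by exact primer prefix; strip the primer.

    Primers must be mutually non-prefixing so every read has at most one
    possible assignment. Returns the per-viewpoint payload lists and the
    number of reads matching no primer (dropped).
    """
    primers = [(vp.primer.upper(), vp.snp_id) for vp in viewpoints]
    for p_a, id_a in primers:
        for p_b, id_b in primers:
            if id_a != id_b and p_a.startswith(p_b):
                raise ValueError(
                    f"primer of {id_b} is a prefix of primer of {id_a}; "
                    "demultiplexing would be ambiguous"
                )
    assigned: dict[str, list[str]] = {vp.snp_id: [] for vp in viewpoints}
    n_unassigned = 0
    for read in reads:
        seq = (read[1] if isinstance(read, tuple) else str(read)).upper()
        for primer, snp_id in primers:
            if seq.startswith(primer):
                assigned[snp_id].append(seq[len(primer):])
                break
        else:
            n_unassigned += 1
    return assigned, n_unassigned


def map_reads(
    payloads,
    library: FragendLibrary,
    viewpoint: ViewpointSpec,
    cell_type: str = "NA",
) -> CoverageProfile:
    """Map primer-stripped payloads exactly to unique fragend 16-mers.

    Each payload is trimmed to its first ``library.flank`` bases and looked
    up against the unique-fragend index; no mismatches are allowed and reads
    matching zero or multiple fragends (i.e. a non-unique 16-mer) are
    discarded and counted. The returned profile covers the usable fragends
    of the viewpoint chromosome; counts landing on other chromosomes are
    retained in ``trans_counts``.
    """
    if viewpoint.chrom not in library.chroms:
        raise ValueError(f"viewpoint chromosome {viewpoint.chrom!r} not in library")
    flank = library.flank
    index = library.seq_index
    counts: dict[str, np.ndarray] = {
        chrom: np.zeros(len(library.usable(chrom)), dtype=np.int64)
        for chrom in library.chroms
    }
    n_mapped = 0
    n_discarded = 0
    payloads = list(payloads)
    if not payloads:
        warnings.warn(f"{viewpoint.snp_id}/{cell_type}: empty read set, empty profile")
    for payload in payloads:
        kmer = str(payload)[:flank].upper()
        hit = index.get(kmer) if len(kmer) == flank else None
        if hit is None:
            n_discarded += 1
            continue
        chrom, i = hit
        counts[chrom][i] += 1
        n_mapped += 1
    usable = library.usable(viewpoint.chrom)
    trans = {c: a for c, a in counts.items() if c != viewpoint.chrom and a.any()}
    return CoverageProfile(
        viewpoint=viewpoint,
        cell_type=cell_type,
        chrom=viewpoint.chrom,
        starts=usable["start"].to_numpy(),
        ends=usable["end"].to_numpy(),
        counts=counts[viewpoint.chrom],
        seqs=tuple(usable["seq"]),
        trans_counts=trans or None,
        stats={
            "n_reads": len(payloads),
            "n_mapped": n_mapped,
            "n_discarded": n_discarded,
        },
    )


def write_coverage_bed(profile: CoverageProfile, path) -> None:
    """Write one BED record per usable fragend, score = 0/1 covered status."""
    status = profile.status
    with open(path, "w") as fh:
        fh.write(
            f"# 4C fragend coverage viewpoint={profile.viewpoint.snp_id} "
            f"cell_type={profile.cell_type} chrom={profile.chrom}\n"
        )
        for start, end, st in zip(profile.starts, profile.ends, status):
            fh.write(
                f"{profile.chrom}\t{start}\t{end}\t"
                f"{profile.viewpoint.snp_id}\t{int(st)}\n"
            )


def read_coverage_bed(path) -> pd.DataFrame:
    """Read a coverage BED back into a (chrom, start, end, name, status) table."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "status"],
        dtype={"chrom": str},
    )
    return df
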