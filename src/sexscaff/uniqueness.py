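"""Sliding-window genome-uniqueness scan.

Male-specific PCR assays and X-chromosome FISH probes both require sequence
that occurs nowhere else in the assembly: a primer or probe landing in a
repeat shared between the Y, the X and/or autosomes would amplify (or paint)
in both sexes.  The scan tiles candidate scaffolds with fixed windows (1 kb
at 0.5 kb offsets for PCR targets, 10 kb for probes), asks for each window
whether it shares sequence with any *other* scaffold, and merges the windows
with no cross-scaffold hits into unique regions.  Matches back to the
window's own scaffold, at any locus, never disqualify it.

Two match engines are provided: ``kmer_exact`` declares a cross-scaffold hit
whenever a window shares a contiguous exact match of at least
``min_shared_exact_match_bp`` bases (either strand) with another scaffold —
a match of length >= L exists iff a shared substring of length exactly L
exists, so a length-L substring index decides this exactly; and
``blast_tabular_import``, which reads a standard 12-column BLAST outfmt-6
self-search instead of searching at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "MatchEngine",
    "MatchEngineParams",
    "GenomeWindow",
    "UniqueRegion",
    "KmerIndex",
    "enumerate_windows",
    "find_cross_scaffold_matches",
    "flag_unique_windows",
    "flag_unique_windows_from_blast",
    "parse_blast_tabular",
    "merge_unique_regions",
    "scaffold_has_unique_region",
    "count_scaffolds_with_unique",
    "select_assay_regions",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCATGCANN")

PCR_WINDOW_BP = 1_000
PCR_OFFSET_BP = 500
PROBE_WINDOW_BP = 10_000


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MatchEngine(str, Enum):
    KMER_EXACT = "kmer_exact"
    BLAST_TABULAR_IMPORT = "blast_tabular_import"


@dataclass(frozen=True)
class MatchEngineParams:
    engine: MatchEngine = MatchEngine.KMER_EXACT
    min_shared_exact_match_bp: int = 50
    window_size_bp: int = PCR_WINDOW_BP
    offset_bp: int = PCR_OFFSET_BP

    def __post_init__(self) -> None:
        if self.offset_bp > self.window_size_bp:
            raise ValueError("offset_bp must not exceed window_size_bp")
        if self.offset_bp < 1:
            raise ValueError("offset_bp must be >= 1")
        if self.min_shared_exact_match_bp < 20:
            raise ValueError("min_shared_exact_match_bp must be >= 20")


@dataclass
class GenomeWindow:
    """Half-open, 0-based window of one scaffold."""

    scaffold_id: str
    start: int
    end: int
    is_unique: bool | None = None
    matched_scaffolds: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad window coordinates [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def window_id(self) -> str:
        return f"{self.scaffold_id}:{self.start}-{self.end}"


@dataclass(frozen=True)
class UniqueRegion:
    """Maximal run of overlapping/abutting unique windows, half-open."""

    scaffold_id: str
    start: int
    end: int
    n_windows_merged: int

    @property
    def length(self) -> int:
        return self.end - self.start


def enumerate_windows(
    lengths: dict[str, int], window_size: int, offset: int
) -> list[GenomeWindow]:
    """Tile each scaffold with windows starting at 0, offset, 2*offset, ...

    A final truncated window is emitted iff it is at least ``offset`` long;
    a scaffold shorter than ``offset`` yields a single whole-scaffold window.
    """
    if not (1 <= offset <= window_size):
        raise ValueError("need window_size >= offset >= 1")
    windows: list[GenomeWindow] = []
    for sid, length in lengths.items():
        length = int(length)
        if length < 1:
            raise ValueError(f"scaffold {sid!r} has non-positive length")
        if length < offset:
            windows.append(GenomeWindow(sid, 0, length))
            continue
        start = 0
        while start < length:
            end = min(start + window_size, length)
            if end - start >= offset:
                windows.append(GenomeWindow(sid, start, end))
            start += offset
    return windows


class KmerIndex:
    """Substring index of a genome at a fixed match length k.

    Maps every k-long substring of every scaffold (forward strand, N-free)
    to the set of scaffolds carrying it.  Queries check a window's forward
    and reverse-complement k-mers, which covers matches on either strand.
    """

    def __init__(self, genome: dict[str, str], k: int) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.genome = {sid: seq.upper() for sid, seq in genome.items()}
        index: dict[str, set[str]] = {}
        for sid, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                hit = index.get(kmer)
                if hit is None:
                    index[kmer] = {sid}
                else:
                    hit.add(sid)
        self._index = index

    def window_matches(self, window: GenomeWindow) -> set[str]:
        """Scaffolds (other than the window's own) sharing a k-mer with it."""
        seq = self.genome.get(window.scaffold_id)
        if seq is None:
            raise KeyError(f"unknown scaffold {window.scaffold_id!r}")
        if window.end > len(seq):
            raise ValueError(
                f"window {window.window_id} exceeds scaffold length {len(seq)}"
            )
        own = window.scaffold_id
        matched: set[str] = set()
        wseq = seq[window.start : window.end]
        for s in (wseq, reverse_complement(wseq)):
            for i in range(len(s) - self.k + 1):
                hit = self._index.get(s[i : i + self.k])
                if hit:
                    matched.update(hit)
        matched.discard(own)
        return matched


def find_cross_scaffold_matches(
    window: GenomeWindow,
    genome: dict[str, str],
    params: MatchEngineParams = MatchEngineParams(),
    index: KmerIndex | None = None,
) -> set[str]:
    """Scaffolds sharing an exact match >= min length with the window.

    ``index`` may be passed to reuse one genome index across many windows.
    """
    if index is None:
        index = KmerIndex(genome, params.min_shared_exact_match_bp)
    return index.window_matches(window)


def flag_unique_windows(
    windows: list[GenomeWindow],
    genome: dict[str, str],
    params: MatchEngineParams = MatchEngineParams(),
) -> list[GenomeWindow]:
    """Set is_unique on every window: unique = no cross-scaffold match."""
    index = KmerIndex(genome, params.min_shared_exact_match_bp)
    for w in windows:
        w.matched_scaffolds = index.window_matches(w)
        w.is_unique = not w.matched_scaffolds
    return windows


def parse_blast_tabular(path: str) -> dict[str, set[str]]:
    """Window id -> subject scaffolds, from a BLAST outfmt-6 self-search.

    Query ids must be window ids of the form ``scaffold:start-end``.
    """
    hits: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"line {ln}: expected 12 outfmt-6 columns")
            qseqid, sseqid = parts[0], parts[1]
            if ":" not in qseqid or "-" not in qseqid.rsplit(":", 1)[1]:
                raise ValueError(
                    f"line {ln}: qseqid {qseqid!r} is not 'scaffold:start-end'"
                )
            hits.setdefault(qseqid, set()).add(sseqid)
    return hits


def flag_unique_windows_from_blast(
    windows: list[GenomeWindow], blast_path: str
) -> list[GenomeWindow]:
    """Flag windows from an externally run BLAST self-search (outfmt 6)."""
    hits = parse_blast_tabular(blast_path)
    for w in windows:
        subjects = hits.get(w.window_id, set())
        w.matched_scaffolds = subjects - {w.scaffold_id}
        w.is_unique = not w.matched_scaffolds
    return windows


def merge_unique_regions(windows: list[GenomeWindow]) -> list[UniqueRegion]:
    """Union overlapping/abutting unique windows into disjoint regions."""
    by_scaffold: dict[str, list[GenomeWindow]] = {}
    for w in windows:
        if w.is_unique is None:
            raise ValueError(f"window {w.window_id} has not been flagged")
        if w.is_unique:
            by_scaffold.setdefault(w.scaffold_id, []).append(w)
    regions: list[UniqueRegion] = []
    for sid in sorted(by_scaffold):
        ws = sorted(by_scaffold[sid], key=lambda w: (w.start, w.end))
        cur_start, cur_end, n = ws[0].start, ws[0].end, 1
        for w in ws[1:]:
            if w.start <= cur_end:  # overlap or abut
                cur_end = max(cur_end, w.end)
                n += 1
            else:
                regions.append(UniqueRegion(sid, cur_start, cur_end, n))
                cur_start, cur_end, n = w.start, w.end, 1
        regions.append(UniqueRegion(sid, cur_start, cur_end, n))
    return regions


def scaffold_has_unique_region(
    scaffold_id: str, regions: list[UniqueRegion]
) -> bool:
    return any(r.scaffold_id == scaffold_id for r in regions)


def count_scaffolds_with_unique(
    regions: list[UniqueRegion], scaffold_set: set[str] | None = None
) -> int:
    """Number of (candidate) scaffolds carrying at least one unique region."""
    with_regions = {r.scaffold_id for r in regions}
    if scaffold_set is not None:
        with_regions &= set(scaffold_set)
    return len(with_regions)


def select_assay_regions(
    regions: list[UniqueRegion],
    min_region_bp: int = 1_000,
    max_regions_per_scaffold: int = 3,
) -> list[UniqueRegion]:
    """Pick regions for primer/probe design: long enough, longest first,
    capped per scaffold; ties broken by start coordinate."""
    chosen: list[UniqueRegion] = []
    by_scaffold: dict[str, list[UniqueRegion]] = {}
    for r in regions:
        if r.length >= min_region_bp:
            by_scaffold.setdefault(r.scaffold_id, []).append(r)
    for sid in sorted(by_scaffold):
        rs = sorted(by_scaffold[sid], key=lambda r: (-r.length, r.start))
        chosen.extend(rs[:max_regions_per_scaffold])
    return chosen
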