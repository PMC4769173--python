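"""Seeded synthetic genomes, coverage tables and qPCR datasets with truth.

The generator emulates the structure of the study system: an assembly of
autosomal, X-derived and Y-derived scaffolds; repeat families shared between
the Y and the X and/or autosomes (the reason Y scaffolds attract female
reads and fail uniqueness scans); and male/female resequencing coverage with
ploidy effects — one X copy in males halves X coverage, Y scaffolds get male
reads only, except for repeat-driven cross-mapping leakage into females.
qPCR simulation reproduces the 2-fold copy effect of X loci in females.

Everything is reproducible from a single integer seed; per-component
generators are derived from it so the genome, the coverage and the qPCR
arms can be re-simulated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageTable, SampleInfo
from .qpcr import AmplificationCurve, QpcrAssay

__all__ = [
    "RepeatFamilySpec",
    "GenomeSpec",
    "RepeatPlacement",
    "SyntheticTruth",
    "CoverageSimParams",
    "generate_genome",
    "simulate_coverage",
    "simulate_qpcr",
    "simulate_amplification_curve",
]

BASES = np.array(list("ACGT"))

AUTO, X, Y = "AUTO", "X", "Y"


@dataclass(frozen=True)
class RepeatFamilySpec:
    """One repeat family: unit length, copy number and where copies go.

    ``placement`` lists the scaffold classes the family may land on; a
    family on both Y and X (or Y and AUTO) is what makes Y windows
    non-unique and leaks female reads onto Y scaffolds.
    """

    unit_bp: int
    n_copies: int
    placement: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.unit_bp < 1 or self.n_copies < 0:
            raise ValueError("bad repeat family spec")
        if not set(self.placement) <= {AUTO, X, Y}:
            raise ValueError(f"unknown placement classes in {self.placement}")


def _default_families() -> tuple[RepeatFamilySpec, ...]:
    # three shared families: X/Y, AUTO/Y and genome-wide
    return (
        RepeatFamilySpec(unit_bp=800, n_copies=10, placement=(X, Y)),
        RepeatFamilySpec(unit_bp=1200, n_copies=10, placement=(AUTO, Y)),
        RepeatFamilySpec(unit_bp=400, n_copies=12, placement=(AUTO, X, Y)),
    )


@dataclass(frozen=True)
class GenomeSpec:
    """Synthetic assembly layout.

    Scaffold lengths are log-uniform on [min_bp, max_bp].  A fraction of Y
    scaffolds is repeat-saturated — tiled end to end with shared repeat
    units, so no window of them is unique (mirroring the majority of real Y
    candidates, which carry repeats in every window); the remaining Y
    scaffolds keep private sequence between randomly placed repeat copies.
    """

    n_autosomal: int = 30
    n_x: int = 6
    n_y: int = 6
    min_bp: int = 5_000
    max_bp: int = 200_000
    gc: float = 0.4
    repeat_families: tuple[RepeatFamilySpec, ...] = field(
        default_factory=_default_families
    )
    y_repeat_saturated_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_autosomal, self.n_x, self.n_y) < 0:
            raise ValueError("scaffold counts must be >= 0")
        if self.min_bp < 1_000:
            raise ValueError("scaffold lengths must be >= 1 kb")
        if self.min_bp > self.max_bp:
            raise ValueError("min_bp > max_bp")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0, 1)")
        if not (0.0 <= self.y_repeat_saturated_fraction <= 1.0):
            raise ValueError("y_repeat_saturated_fraction must be in [0, 1]")


@dataclass(frozen=True)
class RepeatPlacement:
    family: int
    scaffold_id: str
    start: int  # 0-based; unit spans [start, start + unit_bp)


@dataclass
class SyntheticTruth:
    """Ground truth for a generated assembly."""

    classes: dict[str, str]  # scaffold id -> AUTO / X / Y
    lengths: dict[str, int]
    placements: list[RepeatPlacement]
    private_intervals: dict[str, list[tuple[int, int]]]
    seed: int

    def scaffolds_of_class(self, cls: str) -> list[str]:
        return [s for s, c in self.classes.items() if c == cls]

    def repeat_bp(self, scaffold_id: str) -> int:
        """Total bases of a scaffold covered by repeat units (union)."""
        length = self.lengths[scaffold_id]
        ivs = sorted(
            (p.start, min(p.start + self._unit_bp[p.family], length))
            for p in self.placements
            if p.scaffold_id == scaffold_id
        )
        total, cur_s, cur_e = 0, None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        return total

    # filled by generate_genome
    _unit_bp: dict[int, int] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.arange(4), size=length, p=p)


def generate_genome(spec: GenomeSpec) -> tuple[dict[str, str], SyntheticTruth]:
    """Generate a FASTA-ready genome dict and its ground truth.

    Background sequence is i.i.d. at the specified GC; repeat-family units
    are random sequences copied verbatim (no divergence) to scaffolds of
    their placement classes.  Deterministic for a fixed spec (seed
    included); truth records every repeat placement and the complementary
    private intervals of each scaffold.
    """
    rng = np.random.default_rng(spec.seed)
    ids: list[str] = []
    classes: dict[str, str] = {}
    lengths: dict[str, int] = {}
    n_total = spec.n_autosomal + spec.n_x + spec.n_y
    cls_list = [AUTO] * spec.n_autosomal + [X] * spec.n_x + [Y] * spec.n_y
    log_lo, log_hi = np.log(spec.min_bp), np.log(spec.max_bp)
    for i in range(n_total):
        sid = f"scf{i:05d}_{cls_list[i]}"
        ids.append(sid)
        classes[sid] = cls_list[i]
        lengths[sid] = int(np.exp(rng.uniform(log_lo, log_hi)))

    seqs = {sid: _random_seq(rng, lengths[sid], spec.gc) for sid in ids}

    units = [
        _random_seq(rng, fam.unit_bp, spec.gc)
        for fam in spec.repeat_families
    ]
    placements: list[RepeatPlacement] = []
    by_class: dict[str, list[str]] = {c: [] for c in (AUTO, X, Y)}
    for sid in ids:
        by_class[classes[sid]].append(sid)

    y_ids = by_class[Y]
    n_saturated = int(round(spec.y_repeat_saturated_fraction * len(y_ids)))
    saturated = set(y_ids[:n_saturated])

    # scattered copies: each family drops its copies on random scaffolds of
    # its placement classes (saturated Y scaffolds handled separately below)
    for fi, fam in enumerate(spec.repeat_families):
        hosts = [
            sid
            for cls in fam.placement
            for sid in by_class[cls]
            if sid not in saturated and lengths[sid] > fam.unit_bp
        ]
        if not hosts:
            continue
        for _ in range(fam.n_copies):
            sid = hosts[rng.integers(len(hosts))]
            start = int(rng.integers(0, lengths[sid] - fam.unit_bp + 1))
            seqs[sid][start : start + fam.unit_bp] = units[fi]
            placements.append(RepeatPlacement(fi, sid, start))

    # saturated Y scaffolds: tiled end to end with shared repeat units
    y_families = [
        fi for fi, fam in enumerate(spec.repeat_families) if Y in fam.placement
    ]
    for sid in saturated:
        if not y_families:
            break
        pos = 0
        while pos < lengths[sid]:
            fi = y_families[int(rng.integers(len(y_families)))]
            unit = units[fi]
            end = min(pos + len(unit), lengths[sid])
            seqs[sid][pos:end] = unit[: end - pos]
            placements.append(RepeatPlacement(fi, sid, pos))
            pos = end

    private: dict[str, list[tuple[int, int]]] = {}
    for sid in ids:
        ivs = sorted(
            (
                p.start,
                min(p.start + spec.repeat_families[p.family].unit_bp, lengths[sid]),
            )
            for p in placements
            if p.scaffold_id == sid
        )
        gaps: list[tuple[int, int]] = []
        cursor = 0
        for s, e in ivs:
            if s > cursor:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < lengths[sid]:
            gaps.append((cursor, lengths[sid]))
        private[sid] = gaps

    genome = {sid: "".join(BASES[seqs[sid]]) for sid in ids}
    truth = SyntheticTruth(
        classes=classes,
        lengths=lengths,
        placements=placements,
        private_intervals=private,
        seed=spec.seed,
        _unit_bp={fi: fam.unit_bp for fi, fam in enumerate(spec.repeat_families)},
    )
    return genome, truth


@dataclass(frozen=True)
class CoverageSimParams:
    """Coverage simulation: Poisson read counts with ploidy effects.

    Expected count = depth * length * ploidy / read_length, with ploidy 1
    for autosomes (both sexes), 1 female / 0.5 male for X, 0.5 male for Y.
    Females receive no Y reads except cross-mapping leakage: a Poisson mass
    of depth * repeat_bp * cross_mapping_fraction / read_length from repeats
    shared with female-carried chromosomes.
    """

    depth: float = 40.0
    read_length_bp: dict[str, int] = field(default_factory=dict)
    cross_mapping_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0.0 <= self.cross_mapping_fraction < 1.0):
            raise ValueError("cross_mapping_fraction must be in [0, 1)")


# study design: one male at 125 bp reads, two females at 95 bp
DEFAULT_SAMPLES = (
    SampleInfo("J", "M", 125),
    SampleInfo("A", "F", 95),
    SampleInfo("B", "F", 95),
)


def _ploidy(cls: str, sex: str) -> float:
    if cls == AUTO:
        return 1.0
    if cls == X:
        return 1.0 if sex == "F" else 0.5
    if cls == Y:
        return 0.5 if sex == "M" else 0.0
    raise ValueError(f"unknown class {cls!r}")


def simulate_coverage(
    truth: SyntheticTruth,
    params: CoverageSimParams = CoverageSimParams(),
    samples: tuple[SampleInfo, ...] = DEFAULT_SAMPLES,
    seed: int | None = None,
) -> CoverageTable:
    """Draw a per-scaffold read-count table for the given samples."""
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    ids = list(truth.lengths)
    lengths = pd.Series({sid: truth.lengths[sid] for sid in ids}, dtype=float)
    counts = {}
    for info in samples:
        read_len = params.read_length_bp.get(
            info.sample_id, info.read_length_bp or 100
        )
        mu = np.empty(len(ids))
        for j, sid in enumerate(ids):
            cls = truth.classes[sid]
            mean = (
                params.depth * lengths[sid] * _ploidy(cls, info.sex) / read_len
            )
            if cls == Y and info.sex == "F":
                mean += (
                    params.depth
                    * truth.repeat_bp(sid)
                    * params.cross_mapping_fraction
                    / read_len
                )
            mu[j] = mean
        counts[info.sample_id] = rng.poisson(mu)
    values = pd.DataFrame(counts, index=ids)
    sample_infos = {s.sample_id: s for s in samples}
    return CoverageTable(lengths=lengths, values=values, samples=sample_infos)


def simulate_qpcr(
    target_class: str,
    efficiency: float = 2.0,
    base_ct: float = 24.0,
    base_ct_reference: float = 24.0,
    noise_sd: float = 0.1,
    n_m: int = 12,
    n_f: int = 9,
    n_replicates: int = 3,
    seed: int = 0,
    target_scaffold_id: str = "target",
    reference_scaffold_id: str = "reference",
) -> list[QpcrAssay]:
    """Simulate triplicate C_T data for one target against an AUTO reference.

    Per replicate, C_T = base_ct - log_E(copy_factor) + N(0, noise_sd),
    where copy_factor = 2 for the target in females when the target is
    X-linked (two X copies vs one), and 1 otherwise.  The reference is
    autosomal: copy factor 1 in both sexes.  Defaults mirror the validation
    design: n_m=12 males, n_f=9 females, triplicates, C_T noise 0.1 cycles.
    """
    if target_class not in (AUTO, X, Y):
        raise ValueError(f"unknown target class {target_class!r}")
    rng = np.random.default_rng(seed)
    assays: list[QpcrAssay] = []
    sexes = ["M"] * n_m + ["F"] * n_f
    for i, sex in enumerate(sexes):
        copy_factor = 2.0 if (target_class == X and sex == "F") else 1.0
        mu_t = base_ct - np.log(copy_factor) / np.log(efficiency)
        ct_t = tuple(mu_t + rng.normal(0, noise_sd, n_replicates))
        ct_r = tuple(base_ct_reference + rng.normal(0, noise_sd, n_replicates))
        assays.append(
            QpcrAssay(
                sample_id=f"{sex}{i:02d}",
                sex=sex,
                target_scaffold_id=target_scaffold_id,
                reference_scaffold_id=reference_scaffold_id,
                ct_replicates_target=ct_t,
                ct_replicates_reference=ct_r,
                efficiency_target=efficiency,
                efficiency_reference=efficiency,
            )
        )
    return assays


def simulate_amplification_curve(
    ct: float,
    n_cycles: int = 40,
    steepness: float = 1.0,
    plateau: float = 10.0,
    baseline: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AmplificationCurve:
    """Logistic amplification curve whose SDM crossing point equals ``ct``.

    The second-derivative maximum of a logistic with steepness k sits
    ln((3+sqrt(3))/(3-sqrt(3)))/k cycles before the inflection; the
    inflection is placed accordingly.
    """
    rng = np.random.default_rng(seed)
    offset = np.log((3 + np.sqrt(3)) / (3 - np.sqrt(3))) / steepness
    midpoint = ct + offset
    cycles = np.arange(1, n_cycles + 1, dtype=float)
    f = baseline + plateau / (1.0 + np.exp(-steepness * (cycles - midpoint)))
    if noise_sd > 0:
        f = np.clip(f + rng.normal(0, noise_sd, f.shape), 0, None)
    return AmplificationCurve(cycle=cycles, fluorescence=f)
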