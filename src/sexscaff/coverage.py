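"""Per-scaffold sequencing coverage and male/female log2 fold-difference tables.

Coverage for a scaffold is the classical fold-coverage estimate

    raw = mapped_read_count * read_length / scaffold_length

normalized per sample to the unweighted mean over all scaffolds, so that a
diploid autosomal scaffold sits at ~1 regardless of library size.  Pairwise
log2 ratios of normalized coverage between a male and a female sample are the
raw material for X/Y candidate classification: one X copy in an XY male halves
male coverage (log2 ~ -1), while Y-derived scaffolds attract few or no female
reads (large positive log2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleInfo",
    "CoverageTable",
    "CoverageProfile",
    "RatioTable",
    "compute_raw_coverage",
    "normalize_profile",
    "log2_fold_table",
]

# In normalized-coverage units; must sit well below genuine low-coverage
# signal (repeat-driven female leakage onto Y scaffolds is ~0.05 of the
# genome average), or the pseudocount itself suppresses true >=7-fold ratios.
DEFAULT_PSEUDOCOUNT = 0.01


@dataclass(frozen=True)
class SampleInfo:
    """Per-sample metadata: sex is 'M', 'F' or 'U' (unknown)."""

    sample_id: str
    sex: str = "U"
    read_length_bp: int | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F", "U"):
            raise ValueError(f"sex must be M, F or U, got {self.sex!r}")
        if self.read_length_bp is not None and self.read_length_bp <= 0:
            raise ValueError("read_length_bp must be positive")


class CoverageTable:
    """Per-scaffold lengths plus per-sample mapped read counts (or coverages).

    Parameters
    ----------
    lengths
        Series of scaffold length (bp) indexed by scaffold id.
    values
        DataFrame indexed by scaffold id, one column per sample, holding
        mapped read counts (default) or precomputed fold-coverage values
        (``precomputed=True``).
    samples
        ``SampleInfo`` for every column of ``values``.  ``read_length_bp``
        is required per sample unless coverages are precomputed.
    precomputed
        If True, ``values`` already holds raw coverage and the
        count * read_length / length step is skipped.
    """

    def __init__(
        self,
        lengths: pd.Series,
        values: pd.DataFrame,
        samples: dict[str, SampleInfo],
        precomputed: bool = False,
    ) -> None:
        lengths = pd.Series(lengths, dtype=float)
        if lengths.index.has_duplicates:
            dups = lengths.index[lengths.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate scaffold ids: {dups}")
        if (lengths < 1).any():
            bad = lengths.index[lengths < 1].tolist()
            raise ValueError(f"scaffold length must be >= 1 bp: {bad}")
        if not values.index.equals(lengths.index):
            values = values.reindex(lengths.index)
            if values.isna().any().any():
                raise ValueError("values missing for some scaffolds in lengths")
        if (values < 0).any().any():
            raise ValueError("read counts / coverages must be non-negative")
        missing = set(values.columns) - set(samples)
        if missing:
            raise ValueError(f"no SampleInfo for samples: {sorted(missing)}")
        if not precomputed:
            for sid in values.columns:
                if samples[sid].read_length_bp is None:
                    raise ValueError(
                        f"read_length_bp required for sample {sid!r} "
                        "when ingesting read counts"
                    )
        self.lengths = lengths
        self.values = values.astype(float)
        self.samples = dict(samples)
        self.precomputed = bool(precomputed)

    @property
    def scaffold_ids(self) -> list[str]:
        return list(self.lengths.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_by_sex(self, sex: str) -> list[str]:
        return [s for s in self.sample_ids if self.samples[s].sex == sex]


@dataclass
class CoverageProfile:
    """Raw and (optionally) mean-scaled coverage of one sample.

    ``normalized`` is raw coverage divided by the mean raw coverage over
    ``norm_set`` (all scaffolds by default), so its mean over that set is 1.
    """

    sample_id: str
    raw: pd.Series
    normalized: pd.Series | None = None
    norm_set: list[str] | None = None

    @property
    def is_normalized(self) -> bool:
        return self.normalized is not None


@dataclass
class RatioTable:
    """Per-scaffold log2 of the normalized-coverage ratio of a sample pair."""

    numerator_sample: str
    denominator_sample: str
    log2_fold: pd.Series
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    # scaffolds where the denominator was exactly 0 and pseudocount 0 (+inf)
    infinite: list[str] = field(default_factory=list)

    @property
    def fold(self) -> pd.Series:
        """Linear-scale fold ratio, 2**log2_fold."""
        return np.exp2(self.log2_fold)


def compute_raw_coverage(table: CoverageTable, sample_id: str) -> CoverageProfile:
    """Fold-coverage of every scaffold for one sample.

    raw = mapped_read_count * read_length_bp / scaffold_length_bp; if the
    table was built from precomputed coverages the stored values are returned
    as-is.
    """
    if sample_id not in table.values.columns:
        raise KeyError(f"unknown sample id: {sample_id!r}")
    col = table.values[sample_id]
    if table.precomputed:
        raw = col.copy()
    else:
        read_len = table.samples[sample_id].read_length_bp
        raw = col * float(read_len) / table.lengths
    raw.name = sample_id
    return CoverageProfile(sample_id=sample_id, raw=raw)


def normalize_profile(
    profile: CoverageProfile,
    scaffold_set: list[str] | None = None,
    length_weighted: bool = False,
    lengths: pd.Series | None = None,
) -> CoverageProfile:
    """Scale a profile so its mean coverage over ``scaffold_set`` is 1.

    The default normalizes to the unweighted mean over all scaffolds in the
    profile.  ``scaffold_set`` restricts the set the mean is taken over (e.g.
    only scaffolds >= 10 kb); values for all scaffolds are still returned.
    ``length_weighted=True`` uses the length-weighted mean instead and
    requires ``lengths``.  Idempotent: renormalizing changes nothing.
    """
    base = profile.normalized if profile.is_normalized else profile.raw
    if scaffold_set is None:
        subset = base
    else:
        missing = set(scaffold_set) - set(base.index)
        if missing:
            raise KeyError(f"scaffold_set ids absent from profile: {sorted(missing)}")
        subset = base.loc[list(scaffold_set)]
    if length_weighted:
        if lengths is None:
            raise ValueError("length_weighted normalization requires lengths")
        w = lengths.loc[subset.index]
        mean = float(np.average(subset, weights=w))
    else:
        mean = float(subset.mean())
    if mean == 0.0:
        raise ValueError("degenerate profile: all coverages zero")
    norm = base / mean
    return CoverageProfile(
        sample_id=profile.sample_id,
        raw=profile.raw,
        normalized=norm,
        norm_set=list(scaffold_set) if scaffold_set is not None else None,
    )


def log2_fold_table(
    num: CoverageProfile,
    den: CoverageProfile,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> RatioTable:
    """Per-scaffold log2((num + p) / (den + p)) of normalized coverage.

    With ``pseudocount=0`` a zero denominator yields a +inf sentinel (flagged
    in ``RatioTable.infinite``); the default pseudocount keeps male-only
    scaffolds finite while ranking zero-female scaffolds highest.
    """
    if not (num.is_normalized and den.is_normalized):
        raise ValueError("both profiles must be normalized first")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    a, b = num.normalized, den.normalized
    if not a.index.equals(b.index):
        sym = sorted(set(a.index).symmetric_difference(b.index))
        raise ValueError(f"mismatched scaffold sets; symmetric difference: {sym}")
    with np.errstate(divide="ignore", invalid="ignore"):
        lf = np.log2((a + pseudocount) / (b + pseudocount))
    infinite = lf.index[np.isinf(lf)].tolist()
    return RatioTable(
        numerator_sample=num.sample_id,
        denominator_sample=den.sample_id,
        log2_fold=lf,
        pseudocount=float(pseudocount),
        infinite=infinite,
    )
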