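"""Genomic scar scoring from allele-specific copy-number segments.

Homologous recombination deficiency (HRD) is quantified as the sum of three
genomic-instability indices computed per sample from allele-specific
copy-number segments:

* **LOH** — count of maximal loss-of-heterozygosity runs (minor allele 0)
  longer than 15 Mb that do not span a whole chromosome;
* **TAI** — telomeric allelic imbalance: segments with unequal allele
  content that reach a chromosome end without crossing the centromere;
* **LST** — large-scale state transitions: breakpoints between adjacent
  segments each >= 10 Mb, after dropping segments < 3 Mb and merging
  identical-state neighbours.

A sample is called HRD when the sum strictly exceeds a threshold
(default 25); otherwise it is considered homologous-recombination
proficient (HRR). The size parameters (15 Mb, 10 Mb, 3 Mb) are the
canonical published scar definitions and are exposed as arguments.

The module also provides the six-state allele-specific segment
classification (HET / NLOH / DLOH / BCNA / ALOH / ASCNA), gene-level
copy-number labelling (Amp / Del / Neutral) and tumor mutational burden.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .genome import MB, GenomeModel

LOH_SIZE_MIN = 15 * MB
LST_BREAK_MIN = 10 * MB
LST_SMOOTH = 3 * MB
HRD_THRESHOLD = 25


@dataclass(frozen=True)
class AlleleSegment:
    """One allele-specific copy-number segment (0-based half-open coordinates).

    ``cn_minor`` is the minor-allele copy count, so ``cn_minor <= cn_total // 2``.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    cn_total: int
    cn_minor: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"segment {self.sample_id}:{self.chrom}:{self.start}-{self.end} "
                "has end <= start"
            )
        if self.start < 0:
            raise ValidationError("segment start must be non-negative")
        if self.cn_total < 0 or self.cn_minor < 0:
            raise ValidationError("copy numbers must be non-negative")
        if self.cn_minor > self.cn_total:
            raise ValidationError(
                f"cn_minor={self.cn_minor} exceeds cn_total={self.cn_total}"
            )
        if self.cn_minor > self.cn_total // 2:
            raise ValidationError(
                f"cn_minor={self.cn_minor} is not the minor allele of "
                f"cn_total={self.cn_total} (must be <= floor(total/2))"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cn_major(self) -> int:
        return self.cn_total - self.cn_minor

    @property
    def is_loh(self) -> bool:
        """Loss of heterozygosity with at least one retained copy."""
        return self.cn_minor == 0 and self.cn_total >= 1

    @property
    def has_allelic_imbalance(self) -> bool:
        return self.cn_minor != self.cn_total - self.cn_minor


class LOHClass(enum.Enum):
    HET = "HET"        # heterozygous two-copy state (1+1)
    NLOH = "NLOH"      # copy-neutral LOH (2+0)
    DLOH = "DLOH"      # LOH with deletion (total <= 1; includes homozygous loss)
    BCNA = "BCNA"      # balanced amplification (k+k, total > 2)
    ALOH = "ALOH"      # amplified LOH (total >= 3, minor 0)
    ASCNA = "ASCNA"    # unbalanced amplification retaining both alleles


def classify_segment_loh(seg: AlleleSegment) -> LOHClass:
    """Six-state allele-specific classification; total over all valid segments."""
    total, minor = seg.cn_total, seg.cn_minor
    if minor > 0:
        if total == 2:
            return LOHClass.HET
        if 2 * minor == total:
            return LOHClass.BCNA
        return LOHClass.ASCNA
    # minor == 0
    if total <= 1:
        return LOHClass.DLOH
    if total == 2:
        return LOHClass.NLOH
    return LOHClass.ALOH


def _by_chrom(segments: Iterable[AlleleSegment]) -> dict[str, list[AlleleSegment]]:
    out: dict[str, list[AlleleSegment]] = {}
    for seg in segments:
        out.setdefault(seg.chrom, []).append(seg)
    for segs in out.values():
        segs.sort(key=lambda s: s.start)
    return out


def compute_loh_count(
    segments: Sequence[AlleleSegment],
    chrom_lengths: Mapping[str, int],
    size_min: int = LOH_SIZE_MIN,
) -> int:
    """Count maximal runs of adjacent LOH segments whose merged length exceeds
    ``size_min`` and which do not span an entire chromosome."""
    count = 0
    for chrom, segs in _by_chrom(segments).items():
        try:
            chrom_len = chrom_lengths[chrom]
        except KeyError:
            raise ValidationError(f"chromosome {chrom!r} absent from genome model") from None
        runs: list[tuple[int, int]] = []
        for seg in segs:
            if seg.end > chrom_len:
                raise ValidationError(
                    f"segment end {seg.end} beyond chromosome {chrom} length {chrom_len}"
                )
            if not seg.is_loh:
                continue
            if runs and runs[-1][1] == seg.start:
                runs[-1] = (runs[-1][0], seg.end)
            else:
                runs.append((seg.start, seg.end))
        for start, end in runs:
            if end - start > size_min and not (start == 0 and end == chrom_len):
                count += 1
    return count


def _merge_identical_adjacent(segs: list[AlleleSegment]) -> list[AlleleSegment]:
    """Merge contiguous segments sharing (cn_total, cn_minor).

    Applied before every scar index so that counts are invariant to how a
    segmentation happens to split an identical-state region."""
    merged: list[AlleleSegment] = []
    for seg in segs:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.end == seg.start
            and (prev.cn_total, prev.cn_minor) == (seg.cn_total, seg.cn_minor)
        ):
            merged[-1] = AlleleSegment(
                seg.sample_id, seg.chrom, prev.start, seg.end, seg.cn_total, seg.cn_minor
            )
        else:
            merged.append(seg)
    return merged


def compute_tai_count(
    segments: Sequence[AlleleSegment],
    genome: GenomeModel,
) -> int:
    """Count allelic-imbalance segments touching a chromosome end that do not
    cross the centromere (i.e. do not span the whole centromere interval).
    Identical-state neighbours are merged first."""
    count = 0
    for chrom, segs in _by_chrom(segments).items():
        chrom_len = genome.length(chrom)
        cen_lo, cen_hi = genome.centromere(chrom)
        for seg in _merge_identical_adjacent(segs):
            if not seg.has_allelic_imbalance:
                continue
            telomeric = seg.start == 0 or seg.end == chrom_len
            crosses = seg.start < cen_lo and seg.end > cen_hi
            if telomeric and not crosses:
                count += 1
    return count


def compute_lst_count(
    segments: Sequence[AlleleSegment],
    break_min: int = LST_BREAK_MIN,
    smooth: int = LST_SMOOTH,
) -> int:
    """Count large-scale state transitions per chromosome.

    Identical-state neighbours are merged, segments shorter than ``smooth``
    dropped, survivors with identical states re-merged, and each breakpoint
    between consecutive remaining segments both >= ``break_min`` counts once.
    """
    count = 0
    for segs in _by_chrom(segments).values():
        merged = _merge_identical_adjacent(segs)
        kept = [s for s in merged if s.length >= smooth]
        runs: list[tuple[int, int, int, int]] = []  # start, end, total, minor
        for seg in kept:
            if runs and (runs[-1][2], runs[-1][3]) == (seg.cn_total, seg.cn_minor):
                runs[-1] = (runs[-1][0], seg.end, seg.cn_total, seg.cn_minor)
            else:
                runs.append((seg.start, seg.end, seg.cn_total, seg.cn_minor))
        for left, right in zip(runs, runs[1:]):
            if (left[1] - left[0]) >= break_min and (right[1] - right[0]) >= break_min:
                count += 1
    return count


@dataclass(frozen=True)
class HRDResult:
    sample_id: str
    loh_count: int
    tai_count: int
    lst_count: int
    hrd_threshold: int = HRD_THRESHOLD

    @property
    def hrd_sum(self) -> int:
        return self.loh_count + self.tai_count + self.lst_count

    @property
    def hrd_status(self) -> str:
        """HRD iff the sum strictly exceeds the threshold; ties are HRR."""
        return "HRD" if self.hrd_sum > self.hrd_threshold else "HRR"


def compute_hrd(
    segments: Sequence[AlleleSegment],
    genome: GenomeModel,
    hrd_threshold: int = HRD_THRESHOLD,
) -> HRDResult:
    """Compute the three scar indices and the HRD call for one sample."""
    samples = {s.sample_id for s in segments}
    if len(samples) != 1:
        raise ValidationError(
            f"compute_hrd expects segments of exactly one sample, got {sorted(samples)}"
        )
    (sample_id,) = samples
    return HRDResult(
        sample_id=sample_id,
        loh_count=compute_loh_count(segments, genome.chrom_lengths),
        tai_count=compute_tai_count(segments, genome),
        lst_count=compute_lst_count(segments),
        hrd_threshold=hrd_threshold,
    )


def compute_hrd_cohort(
    segments: Sequence[AlleleSegment],
    genome: GenomeModel,
    hrd_threshold: int = HRD_THRESHOLD,
) -> pd.DataFrame:
    """Per-sample HRD table with columns loh, tai, lst, sum, status."""
    by_sample: dict[str, list[AlleleSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    rows = []
    for sample_id in sorted(by_sample):
        res = compute_hrd(by_sample[sample_id], genome, hrd_threshold)
        rows.append(
            {
                "sample": sample_id,
                "loh": res.loh_count,
                "tai": res.tai_count,
                "lst": res.lst_count,
                "sum": res.hrd_sum,
                "status": res.hrd_status,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def label_gene_cn(cn_value: float) -> str:
    """Amp iff copy number > 4, Del iff < 1, otherwise Neutral (strict bounds)."""
    if cn_value < 0:
        raise ValidationError(f"negative copy number {cn_value}")
    if cn_value > 4:
        return "Amp"
    if cn_value < 1:
        return "Del"
    return "Neutral"


EFFECT_CLASSES = frozenset({"nonsynonymous", "synonymous", "other"})


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    gene_id: str
    effect_class: str

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValidationError(
                f"unknown effect class {self.effect_class!r}; "
                f"expected one of {sorted(EFFECT_CLASSES)}"
            )


def compute_tmb(mutations: Sequence[MutationRecord], callable_mb: float) -> float:
    """Tumor mutational burden: non-synonymous mutations per callable megabase."""
    if callable_mb <= 0:
        raise ConfigError(f"callable_mb must be positive, got {callable_mb}")
    n = sum(1 for m in mutations if m.effect_class == "nonsynonymous")
    return n / callable_mb


def gene_cn_labels(cn: pd.DataFrame) -> pd.DataFrame:
    """Vectorised Amp/Del/Neutral labels for a genes x samples CN matrix."""
    if (cn.to_numpy() < 0).any():
        raise ValidationError("negative copy number in CN matrix")
    arr = np.full(cn.shape, "Neutral", dtype=object)
    arr[cn.to_numpy() > 4] = "Amp"
    arr[cn.to_numpy() < 1] = "Del"
    return pd.DataFrame(arr, index=cn.index, columns=cn.columns)
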