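"""Genomic coordinate frame: chromosome arms, segments, and their overlap.

All coordinates are 0-based half-open (BED convention) in memory. SEG-dialect
segment files are 1-based inclusive on disk and converted on read/write.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "ChromosomeArm", "ArmTable", "Segment", "SegmentProfile",
    "load_arm_table", "write_arm_table", "default_karyotype",
    "intersect_segments_with_arms", "read_segments", "write_segments",
]

_ACROCENTRIC_P = {"13p", "14p", "15p", "21p", "22p"}


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural ordering: numeric chromosomes first, then lexicographic."""
    c = chrom.removeprefix("chr")
    return (int(c), "") if c.isdigit() else (10**6, c)


@dataclass(frozen=True)
class ChromosomeArm:
    """One chromosome arm as a half-open genomic interval."""

    chrom: str
    arm: str  # "p" or "q"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be 'p' or 'q', got {self.arm!r}")
        if not self.start < self.end:
            raise ValueError(
                f"arm {self.chrom}{self.arm}: start {self.start} must be < end {self.end}"
            )

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ArmTable:
    """Ordered, validated collection of chromosome arms.

    The default karyotype has the 39 autosomal arms commonly used for
    arm-level copy number reporting: 22 autosomes, with the short arms of the
    acrocentric chromosomes 13, 14, 15, 21 and 22 omitted.
    """

    arms: tuple[ChromosomeArm, ...]

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("no arms")
        ordered = tuple(sorted(self.arms, key=lambda a: (_chrom_sort_key(a.chrom), a.start)))
        object.__setattr__(self, "arms", ordered)
        by_chrom: dict[str, list[ChromosomeArm]] = {}
        for a in ordered:
            by_chrom.setdefault(a.chrom, []).append(a)
        for chrom, group in by_chrom.items():
            for prev, cur in zip(group, group[1:]):
                if cur.start < prev.end:
                    raise ValueError(
                        f"overlapping arms on chromosome {chrom}: "
                        f"{prev.name} [{prev.start},{prev.end}) and "
                        f"{cur.name} [{cur.start},{cur.end})"
                    )

    def __len__(self) -> int:
        return len(self.arms)

    def __iter__(self):
        return iter(self.arms)

    def __contains__(self, name: str) -> bool:
        return any(a.name == name for a in self.arms)

    @property
    def total_length(self) -> int:
        return sum(a.length for a in self.arms)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.arms)

    def by_name(self, name: str) -> ChromosomeArm:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(name)


@dataclass(frozen=True)
class Segment:
    """A segmented copy number interval with its observed log2 ratio."""

    chrom: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"segment start {self.start} must be < end {self.end}")
        if not (self.log2_ratio == self.log2_ratio and abs(self.log2_ratio) < float("inf")):
            raise ValueError("log2_ratio must be finite")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentProfile:
    """All segments of one sample; non-overlapping within a chromosome."""

    sample_id: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.segments, key=lambda s: (_chrom_sort_key(s.chrom), s.start))
        )
        object.__setattr__(self, "segments", ordered)
        for prev, cur in zip(ordered, ordered[1:]):
            if cur.chrom == prev.chrom and cur.start < prev.end:
                raise ValueError(
                    f"sample {self.sample_id}: overlapping segments on {cur.chrom} "
                    f"at [{prev.start},{prev.end}) and [{cur.start},{cur.end})"
                )


_ARM_NAME_RE = re.compile(r"^(?P<chrom>.+?)(?P<arm>[pq])$")


def load_arm_table(path: str | Path) -> ArmTable:
    """Read a BED4 arm definition table (chrom, start, end, name like "1p").

    Raises a :class:`ValueError` naming the offending line for malformed
    input, and for overlapping arms on one chromosome.
    """
    arms = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected >=4 BED columns, got {len(fields)}")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            m = _ARM_NAME_RE.match(name)
            if m is None:
                raise ValueError(f"{path}: line {lineno}: arm name {name!r} lacks p/q suffix")
            try:
                arms.append(ChromosomeArm(chrom=chrom, arm=m.group("arm"), start=start, end=end))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    if not arms:
        raise ValueError(f"{path}: no arms")
    return ArmTable(arms=tuple(arms))


def write_arm_table(table: ArmTable, path: str | Path) -> None:
    """Write BED4 (tab-separated, no header); round-trips with load_arm_table."""
    with open(path, "w") as fh:
        for a in table:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.name}\n")


def default_karyotype() -> ArmTable:
    """The packaged 39-arm autosomal karyotype (hg19 cytoband p/q boundaries)."""
    ref = resources.files("purecna.data").joinpath("arms_hg19.bed")
    with resources.as_file(ref) as path:
        table = load_arm_table(path)
    assert len(table) == 39
    return table


def intersect_segments_with_arms(
    profile: SegmentProfile, arms: ArmTable
) -> dict[str, list[tuple[Segment, int]]]:
    """Map each arm name to the segments overlapping it with overlap lengths.

    Segments on chromosomes absent from the arm table are skipped with a
    warning; parts of segments outside all arms (e.g. centromeric gaps of a
    sparser frame) are dropped. Every arm of the table appears as a key, with
    an empty list when uncovered.
    """
    known_chroms = {a.chrom for a in arms}
    result: dict[str, list[tuple[Segment, int]]] = {a.name: [] for a in arms}
    skipped = set()
    for seg in profile.segments:
        if seg.chrom not in known_chroms:
            skipped.add(seg.chrom)
            continue
        for arm in arms:
            if arm.chrom != seg.chrom:
                continue
            overlap = min(seg.end, arm.end) - max(seg.start, arm.start)
            if overlap > 0:
                result[arm.name].append((seg, overlap))
    if skipped:
        warnings.warn(
            f"sample {profile.sample_id}: skipped segments on chromosomes "
            f"absent from arm table: {sorted(skipped)}",
            stacklevel=2,
        )
    return result


# ---------------------------------------------------------------------------
# SEG-dialect I/O: TSV with header, 1-based inclusive coordinates on disk.

_SEG_COLUMNS = ["sample", "chrom", "start", "end", "log2_ratio"]


def read_segments(path: str | Path) -> dict[str, SegmentProfile]:
    """Read a SEG-like TSV into per-sample profiles (coordinates converted)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = [c for c in _SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    profiles = {}
    for sample_id, group in df.groupby("sample", sort=True):
        segments = tuple(
            Segment(chrom=r.chrom, start=int(r.start) - 1, end=int(r.end),
                    log2_ratio=float(r.log2_ratio))
            for r in group.itertuples()
        )
        profiles[str(sample_id)] = SegmentProfile(sample_id=str(sample_id), segments=segments)
    return profiles


def write_segments(profiles: Iterable[SegmentProfile] | Mapping[str, SegmentProfile],
                   path: str | Path) -> None:
    if isinstance(profiles, Mapping):
        profiles = profiles.values()
    with open(path, "w") as fh:
        fh.write("\t".join(_SEG_COLUMNS) + "\n")
        for prof in profiles:
            for s in prof.segments:
                fh.write(
                    f"{prof.sample_id}\t{s.chrom}\t{s.start + 1}\t{s.end}\t{s.log2_ratio:.6g}\n"
                )
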