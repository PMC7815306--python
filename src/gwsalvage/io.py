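"""Domain types and readers/writers for the file formats the pipeline touches.

Coordinate conventions follow the source formats: GWAS summary statistics carry
1-based SNP positions; peaks and restriction fragments are half-open 0-based
(BED convention). Overlap tests convert a SNP position ``p`` to the 0-based
point ``p - 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Genome-wide significance threshold.
GWS_P = 5e-8

#: Extended MHC region (hg19), chr6:28,477,797-33,448,354 (1-based inclusive),
#: stored half-open 0-based. Configurable wherever it is consumed.
MHC_HG19: "GenomicInterval"


@dataclass(frozen=True, slots=True)
class SnpRecord:
    """One summary-statistics row: identifier, position, association p-value."""

    rsid: str
    chrom: str
    pos: int  # 1-based
    pvalue: float

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.rsid}: p-value must be in (0, 1], got {self.pvalue}")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1, got {self.pos}")


class GwasWave:
    """One GWAS release: labelled summary statistics plus its sample size.

    Parameters
    ----------
    label : str
        Free-text release label, e.g. ``"2010"``.
    sample_size : int
        Total GWAS sample size of the release.
    records : iterable of SnpRecord
        Summary statistics; rsids must be unique.
    """

    def __init__(self, label: str, sample_size: int, records: Iterable[SnpRecord]):
        if sample_size <= 0:
            raise ValueError(f"sample_size must be positive, got {sample_size}")
        self.label = label
        self.sample_size = int(sample_size)
        self.records: dict[str, SnpRecord] = {}
        for rec in records:
            if rec.rsid in self.records:
                raise ValueError(f"duplicate rsid in wave {label!r}: {rec.rsid}")
            self.records[rec.rsid] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.records

    def pvalue(self, rsid: str) -> float:
        return self.records[rsid].pvalue

    def gws_snps(self, gws_p: float = GWS_P) -> set[str]:
        """rsids genome-wide significant in this wave (p < ``gws_p``)."""
        return {r for r, rec in self.records.items() if rec.pvalue < gws_p}

    def __repr__(self) -> str:
        return f"GwasWave(label={self.label!r}, n={self.sample_size}, snps={len(self)})"


class LdPanel:
    """Symmetric pairwise r² lookup over SNP identifiers.

    Self-pairs are implied at r² = 1: a SNP with no table entries still has
    itself as its only proxy.
    """

    def __init__(self, pairs: Iterable[tuple[str, str, float]] = ()):
        self._r2: dict[str, dict[str, float]] = {}
        for a, b, r2 in pairs:
            self.add_pair(a, b, r2)

    def add_pair(self, rsid_a: str, rsid_b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must be in [0, 1]: ({rsid_a}, {rsid_b}, {r2})")
        if rsid_a == rsid_b:
            return
        self._r2.setdefault(rsid_a, {})[rsid_b] = r2
        self._r2.setdefault(rsid_b, {})[rsid_a] = r2

    def r2(self, rsid_a: str, rsid_b: str) -> float:
        if rsid_a == rsid_b:
            return 1.0
        return self._r2.get(rsid_a, {}).get(rsid_b, 0.0)

    def partners(self, rsid: str) -> Mapping[str, float]:
        """All SNPs with a recorded pair against ``rsid`` (self excluded)."""
        return self._r2.get(rsid, {})

    def has_ld(self, rsid: str) -> bool:
        """Whether the panel records any pair for ``rsid``."""
        return bool(self._r2.get(rsid))

    def query(self, rsid: str, r2_min: float) -> set[str]:
        """SNPs with r² strictly above ``r2_min`` against ``rsid``, plus itself."""
        out = {b for b, v in self._r2.get(rsid, {}).items() if v > r2_min}
        out.add(rsid)
        return out

    def snps(self) -> set[str]:
        return set(self._r2)

    def iter_pairs(self) -> Iterable[tuple[str, str, float]]:
        """Each unordered pair once, orientation sorted lexicographically."""
        for a, nbrs in self._r2.items():
            for b, r2 in nbrs.items():
                if a < b:
                    yield a, b, r2

    def __len__(self) -> int:
        return sum(1 for _ in self.iter_pairs())


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """Half-open 0-based genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    def contains_point(self, chrom: str, point0: int) -> bool:
        return chrom == self.chrom and self.start <= point0 < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __len__(self) -> int:
        return self.end - self.start


MHC_HG19 = GenomicInterval("chr6", 28_477_796, 33_448_354)


@dataclass(frozen=True, slots=True)
class Fragment:
    """A restriction fragment; baited fragments cover annotated promoters."""

    interval: GenomicInterval
    fragment_id: str
    is_bait: bool = False
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.is_bait and not self.genes:
            raise ValueError(f"baited fragment {self.fragment_id} carries no gene name")
        if not self.is_bait and self.genes:
            raise ValueError(f"non-bait fragment {self.fragment_id} carries gene names")


@dataclass(frozen=True, slots=True)
class Contact:
    """A significant promoter interaction between a bait and an other-end fragment."""

    bait_fragment_id: str
    other_fragment_id: str
    score: float
    resolution: int = 1

    def __post_init__(self) -> None:
        if self.resolution not in (1, 4):
            raise ValueError(f"resolution must be 1 or 4, got {self.resolution}")


class ChromatinContext:
    """Per-cell-type chromatin evidence: ATAC peaks, fragment maps, contacts.

    Fragment maps are held per interaction resolution (1- and 4-fragment maps
    have independent identifier spaces, mirroring the separate rmap/baitmap
    files they are read from).
    """

    def __init__(
        self,
        cell_type: str,
        peaks: Iterable[GenomicInterval],
        fragments: Mapping[int, Mapping[str, Fragment]],
        contacts: Iterable[Contact],
    ):
        self.cell_type = cell_type
        self.peaks: list[GenomicInterval] = list(peaks)
        self.fragments: dict[int, dict[str, Fragment]] = {
            res: dict(frs) for res, frs in fragments.items()
        }
        self.contacts: list[Contact] = list(contacts)
        for c in self.contacts:
            frs = self.fragments.get(c.resolution, {})
            for fid in (c.bait_fragment_id, c.other_fragment_id):
                if fid not in frs:
                    raise ValueError(
                        f"contact references unknown fragment {fid!r} at "
                        f"{c.resolution}-fragment resolution"
                    )
            if not frs[c.bait_fragment_id].is_bait:
                raise ValueError(
                    f"contact bait side {c.bait_fragment_id!r} is not a baited fragment"
                )

    def __repr__(self) -> str:
        nfrag = sum(len(v) for v in self.fragments.values())
        return (
            f"ChromatinContext({self.cell_type!r}, peaks={len(self.peaks)}, "
            f"fragments={nfrag}, contacts={len(self.contacts)})"
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS = {"rsid": "rsid", "chrom": "chrom", "pos": "pos", "pvalue": "p"}


def read_summary_stats(
    path: str | Path,
    label: str,
    sample_size: int,
    columns: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> GwasWave:
    """Read a delimited GWAS summary-statistics table into a :class:`GwasWave`.

    ``columns`` maps the canonical keys (rsid, chrom, pos, pvalue) to the
    file's header names; the releases differ in their headers so the mapping
    is configurable. Rows with missing or invalid p-values (p <= 0, p > 1,
    non-numeric) are dropped, with the count logged.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep=sep, dtype={cols["rsid"]: str, cols["chrom"]: str})
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    p = pd.to_numeric(df[cols["pvalue"]], errors="coerce")
    valid = p.notna() & (p > 0.0) & (p <= 1.0)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning(
            "%s: dropped %d rows with missing/invalid p-values", path, n_dropped
        )
    df = df[valid]
    records = (
        SnpRecord(
            rsid=str(row[cols["rsid"]]),
            chrom=str(row[cols["chrom"]]),
            pos=int(row[cols["pos"]]),
            pvalue=float(row[cols["pvalue"]]),
        )
        for row in df.to_dict("records")
    )
    return GwasWave(label=label, sample_size=sample_size, records=records)


def write_summary_stats(wave: GwasWave, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"rsid": r.rsid, "chrom": r.chrom, "pos": r.pos, "p": r.pvalue}
            for r in wave.records.values()
        ],
        columns=["rsid", "chrom", "pos", "p"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_ld_table(path: str | Path) -> LdPanel:
    """Read a three-column (rsid_a, rsid_b, r2) TSV into a symmetric panel."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["rsid_a", "rsid_b", "r2"], comment="#",
        dtype={"rsid_a": str, "rsid_b": str},
    )
    # tolerate an optional header row
    if len(df) and not pd.api.types.is_number(df["r2"].iloc[0]):
        first = pd.to_numeric(df["r2"].iloc[0], errors="coerce")
        if pd.isna(first):
            df = df.iloc[1:]
    panel = LdPanel()
    for a, b, r2 in df.itertuples(index=False):
        panel.add_pair(str(a), str(b), float(r2))
    return panel


def write_ld_table(panel: LdPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b, r2 in sorted(panel.iter_pairs()):
            fh.write(f"{a}\t{b}\t{r2:.6g}\n")


def read_peaks(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+/narrowPeak open-chromatin intervals; extra columns ignored."""
    peaks: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            peaks.append(GenomicInterval(chrom, start, end))
    return peaks


def write_peaks(peaks: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda x: (x.chrom, x.start, x.end)):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")


def _read_rmap_rows(path: str | Path, n_extra: int) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4 + n_extra:
                raise ValueError(f"{path}:{lineno}: expected >={4 + n_extra} columns")
            rows.append(fields)
    return rows


def read_contacts(
    baitmap_path: str | Path,
    rmap_path: str | Path,
    ibed_path: str | Path,
    resolution: int = 1,
) -> tuple[dict[str, Fragment], list[Contact]]:
    """Read CHiCAGO-convention fragment maps and significant interactions.

    The rmap carries (chrom, start, end, id); the baitmap repeats the rmap
    columns plus a ";"-separated gene annotation. The ibed table carries the
    bait and other-end coordinates plus read count and score; each end is
    resolved against the rmap by exact coordinates, and an interaction whose
    coordinates are absent from the rmap is an error. Bait-to-bait rows are
    retained here (the constraint step excludes them).
    """
    baits: dict[str, tuple[str, ...]] = {}
    for fields in _read_rmap_rows(baitmap_path, 1):
        genes = tuple(g for g in fields[4].split(";") if g)
        if not genes:
            raise ValueError(f"{baitmap_path}: bait {fields[3]} has no gene annotation")
        baits[fields[3]] = genes

    fragments: dict[str, Fragment] = {}
    by_coord: dict[tuple[str, int, int], str] = {}
    for fields in _read_rmap_rows(rmap_path, 0):
        chrom, start, end, fid = fields[0], int(fields[1]), int(fields[2]), fields[3]
        if fid in fragments:
            raise ValueError(f"{rmap_path}: duplicate fragment id {fid}")
        fragments[fid] = Fragment(
            interval=GenomicInterval(chrom, start, end),
            fragment_id=fid,
            is_bait=fid in baits,
            genes=baits.get(fid, ()),
        )
        by_coord[(chrom, start, end)] = fid
    unknown_baits = set(baits) - set(fragments)
    if unknown_baits:
        raise ValueError(f"{baitmap_path}: baits missing from rmap: {sorted(unknown_baits)}")

    contacts: list[Contact] = []
    with open(ibed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "bait_chr")):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"{ibed_path}:{lineno}: expected >=10 ibed columns")
            bait_key = (f[0], int(f[1]), int(f[2]))
            oe_key = (f[4], int(f[5]), int(f[6]))
            for key, side in ((bait_key, "bait"), (oe_key, "other end")):
                if key not in by_coord:
                    raise ValueError(
                        f"{ibed_path}:{lineno}: {side} {key[0]}:{key[1]}-{key[2]} "
                        f"not present in rmap"
                    )
            bait_id = by_coord[bait_key]
            if not fragments[bait_id].is_bait:
                raise ValueError(
                    f"{ibed_path}:{lineno}: bait side {bait_id} is not in the baitmap"
                )
            contacts.append(
                Contact(
                    bait_fragment_id=bait_id,
                    other_fragment_id=by_coord[oe_key],
                    score=float(f[9]),
                    resolution=resolution,
                )
            )
    return fragments, contacts


def write_contacts(
    fragments: Mapping[str, Fragment],
    contacts: Sequence[Contact],
    baitmap_path: str | Path,
    rmap_path: str | Path,
    ibed_path: str | Path,
) -> None:
    """Write fragments/contacts back out in the rmap/baitmap/ibed dialects."""
    order = sorted(
        fragments.values(), key=lambda fr: (fr.interval.chrom, fr.interval.start)
    )
    with open(rmap_path, "w") as fh:
        for fr in order:
            iv = fr.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{fr.fragment_id}\n")
    with open(baitmap_path, "w") as fh:
        for fr in order:
            if fr.is_bait:
                iv = fr.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{fr.fragment_id}\t"
                    f"{';'.join(fr.genes)}\n"
                )
    with open(ibed_path, "w") as fh:
        fh.write(
            "bait_chr\tbait_start\tbait_end\tbait_name\totherEnd_chr\t"
            "otherEnd_start\totherEnd_end\totherEnd_name\tN_reads\tscore\n"
        )
        for c in contacts:
            b = fragments[c.bait_fragment_id]
            o = fragments[c.other_fragment_id]
            fh.write(
                f"{b.interval.chrom}\t{b.interval.start}\t{b.interval.end}\t"
                f"{';'.join(b.genes)}\t{o.interval.chrom}\t{o.interval.start}\t"
                f"{o.interval.end}\t{o.fragment_id}\t0\t{c.score:g}\n"
            )
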