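"""CNV tables, gene-interval intersection, and benign-overlap scoring.

Coordinates are 0-based half-open (BED convention) throughout;
``length = end - start``.  A CNV is assigned every gene whose interval
overlaps it by at least 1 bp.  The benign-overlap score mirrors how
catalogs of variants from presumed-healthy individuals (DGV-style) are
used as negative evidence: within each contributing study the reported
regions are merged, and a query CNV accumulates, over all studies, the
fractional overlap of every merged region that covers at least half of
the CNV's length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

__all__ = [
    "CNVRecord",
    "GeneModels",
    "DGVStudySet",
    "read_cnv_table",
    "read_gene_models",
    "read_dgv_table",
    "map_cnv_genes",
    "merge_study_regions",
    "dgv_frequency",
]

logger = logging.getLogger(__name__)


@dataclass
class CNVRecord:
    """One CNV call with its phenotype context and derived features."""

    chromosome: str
    start: int
    end: int
    type: str                               # "DUP" | "DEL"
    phenotypes: frozenset[str]
    label: bool | None = None               # True harmful, False benign
    patient: str | None = None
    genes: list[str] = field(default_factory=list)
    dgv_frequency: float | None = None
    causative_gene: bool | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"CNV end must exceed start: {self.chromosome}:{self.start}-{self.end}"
            )
        if self.type not in ("DUP", "DEL"):
            raise ValueError(f"CNV type must be DUP or DEL, got {self.type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class GeneModels:
    """Gene intervals indexed per chromosome for overlap queries."""

    def __init__(self, records: list[tuple[str, int, int, str]]):
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end, gene in records:
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end, gene)

    @property
    def chromosomes(self) -> set[str]:
        return set(self._trees)

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[int, int, str]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end, iv.data) for iv in tree.overlap(start, end))


def map_cnv_genes(cnv: CNVRecord, gene_models: GeneModels) -> list[str]:
    """Genes overlapping the CNV by >= 1 bp, in positional order."""
    if cnv.chromosome not in gene_models.chromosomes:
        logger.warning(
            "chromosome %r not present in gene models; CNV %s:%d-%d gets no genes",
            cnv.chromosome, cnv.chromosome, cnv.start, cnv.end,
        )
        return []
    hits = gene_models.overlapping(cnv.chromosome, cnv.start, cnv.end)
    seen: set[str] = set()
    out: list[str] = []
    for _, _, gene in hits:
        if gene not in seen:
            seen.add(gene)
            out.append(gene)
    return out


def merge_study_regions(regions: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of overlapping-or-touching same-chromosome intervals, sorted."""
    if not regions:
        return []
    ordered = sorted(regions)
    merged = [ordered[0]]
    for start, end in ordered[1:]:
        last_start, last_end = merged[-1]
        if start <= last_end:  # overlap or touch
            merged[-1] = (last_start, max(last_end, end))
        else:
            merged.append((start, end))
    return merged


class DGVStudySet:
    """Benign-variant regions grouped by study, merged within each study."""

    def __init__(self, studies: dict[str, dict[str, list[tuple[int, int]]]]):
        # study -> chromosome -> merged sorted interval list
        self._studies = {
            study: {chrom: merge_study_regions(regs) for chrom, regs in by_chrom.items()}
            for study, by_chrom in studies.items()
        }

    @property
    def studies(self) -> set[str]:
        return set(self._studies)

    def regions(self, study: str, chrom: str) -> list[tuple[int, int]]:
        return self._studies.get(study, {}).get(chrom, [])


def dgv_frequency(
    cnv: CNVRecord, dgv: DGVStudySet, overlap_threshold: float = 0.5
) -> float:
    """Summed fractional overlap of qualifying merged benign regions.

    Over every study's merged regions on the CNV's chromosome, each
    region whose overlap with the CNV reaches ``overlap_threshold`` of
    the CNV's length contributes ``overlap_bp / cnv.length``; the score
    is the sum (so it can exceed 1 when several studies concur).
    """
    gate = overlap_threshold * cnv.length
    total = 0.0
    for study in dgv.studies:
        for start, end in dgv.regions(study, cnv.chromosome):
            ov = min(end, cnv.end) - max(start, cnv.start)
            if ov >= gate and ov > 0:
                total += ov / cnv.length
    return total


# ---------------------------------------------------------------------------
# Readers

_CNV_HEADER = ("chromosome", "start", "end", "type")


def read_cnv_table(path: str) -> list[CNVRecord]:
    """Read a six-column tab-separated CNV table.

    Columns: chromosome, start, end, type [DUP/DEL], phenotype
    (semicolon-joined terms), classification [HARMFUL/BENIGN].  The
    classification column may be empty or absent (inference mode), and
    an optional seventh column carries a patient identifier.  A header
    line is detected by a non-numeric ``start`` field.  Malformed rows
    are rejected with their line number.
    """
    records: list[CNVRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and len(fields) >= 2 and not fields[1].isdigit():
                continue  # header
            if len(fields) < 5:
                raise ValueError(
                    f"{path}:{lineno}: expected >=5 tab-separated columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            label_field = fields[5].strip().upper() if len(fields) > 5 else ""
            if label_field == "HARMFUL":
                label = True
            elif label_field == "BENIGN":
                label = False
            elif label_field == "":
                label = None
            else:
                raise ValueError(
                    f"{path}:{lineno}: classification must be HARMFUL or BENIGN, "
                    f"got {fields[5]!r}"
                )
            try:
                records.append(
                    CNVRecord(
                        chromosome=fields[0],
                        start=start,
                        end=end,
                        type=fields[3].strip().upper(),
                        phenotypes=frozenset(
                            p.strip() for p in fields[4].split(";") if p.strip()
                        ),
                        label=label,
                        patient=fields[6] if len(fields) > 6 else None,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def read_gene_models(path: str) -> GeneModels:
    """Read BED4 gene models (chrom, start, end, gene_id)."""
    records: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 BED columns")
            records.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
    return GeneModels(records)


def read_dgv_table(path: str) -> DGVStudySet:
    """Read a tab-separated benign-region table (study, chrom, start, end)."""
    studies: dict[str, dict[str, list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
            study, chrom = fields[0], fields[1]
            studies.setdefault(study, {}).setdefault(chrom, []).append(
                (int(fields[2]), int(fields[3]))
            )
    return DGVStudySet(studies)
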