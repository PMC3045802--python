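"""Reading and writing the normalized TSV tables the pipeline exchanges.

Every on-disk table is tab-separated with a header row.  Set-valued cells
(reaction gene/metabolite lists) use ";" as the in-cell delimiter.  Parsers
validate eagerly and never drop rows silently: a row is either returned as a
record, collapsed as a logged duplicate, or rejected with a
:class:`FormatError` naming its position.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger("genevote")

#: interaction layer tags
LAYERS = ("ppi", "metabolic", "regulatory")

#: in-cell delimiter for set-valued TSV fields
SET_DELIMITER = ";"


class FormatError(ValueError):
    """A table violated its format contract (bad column, value, or layer tag)."""


@dataclass(frozen=True, order=True)
class InteractionRecord:
    """One typed gene-gene interaction.

    ppi records are canonicalized so ``source <= target`` lexicographically,
    because the protein-physical layer is undirected; metabolic and
    regulatory records keep their direction.
    """

    source: str
    target: str
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise FormatError(f"unknown layer tag {self.layer!r}")
        if not self.source or not self.target:
            raise FormatError("source and target must be non-empty")

    @classmethod
    def create(cls, source: str, target: str, layer: str) -> "InteractionRecord":
        """Build a record, canonicalizing undirected ppi edge order."""
        if layer == "ppi" and source > target:
            source, target = target, source
        return cls(source, target, layer)


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction of a stoichiometric model.

    ``genes`` lists the catalyzing enzymes and may be empty (a spontaneous
    reaction contributes no enzyme-enzyme interaction); reactants and
    products must be non-empty.
    """

    reaction_id: str
    genes: frozenset[str]
    reactants: frozenset[str]
    products: frozenset[str]

    def __post_init__(self) -> None:
        if not self.reactants or not self.products:
            raise FormatError(
                f"reaction {self.reaction_id!r}: reactants and products must be non-empty"
            )


@dataclass(frozen=True, order=True)
class AnnotationRecord:
    """One gene -> subcellular-localization term assignment."""

    gene: str
    term: str

    def __post_init__(self) -> None:
        if not self.gene:
            raise FormatError("empty gene in annotation")
        if not self.term:
            raise FormatError("empty term in annotation")


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-gene expression vector in tpm units, one value per tissue."""

    gene: str
    tpm: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(v < 0 or math.isnan(v) for v in self.tpm):
            raise FormatError(f"gene {self.gene!r}: negative or NaN tpm value")


def _read_rows(path: str | Path, required: Sequence[str]) -> Iterable[tuple[int, dict]]:
    """Yield (1-based data row number, row dict); validate the header first."""
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
        for i, row in enumerate(reader, start=1):
            if None in row.values() or None in row:
                raise FormatError(f"{path}: row {i}: wrong column count")
            yield i, row


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    """Read an interaction edge list (columns source, target, layer).

    Duplicate edges (after ppi canonicalization) are collapsed and the
    collapsed count is logged.
    """
    records: list[InteractionRecord] = []
    seen: set[InteractionRecord] = set()
    duplicates = 0
    for i, row in _read_rows(path, ("source", "target", "layer")):
        layer = row["layer"].strip()
        if layer not in LAYERS:
            raise FormatError(
                f"{path}: row {i}: unknown layer {layer!r} (expected one of {LAYERS})"
            )
        source, target = row["source"].strip(), row["target"].strip()
        if not source or not target:
            raise FormatError(f"{path}: row {i}: empty source or target")
        rec = InteractionRecord.create(source, target, layer)
        if rec in seen:
            duplicates += 1
        else:
            seen.add(rec)
            records.append(rec)
    if duplicates:
        logger.info("read_interactions(%s): collapsed %d duplicate rows", path, duplicates)
    return records


def _parse_set(cell: str) -> frozenset[str]:
    return frozenset(t.strip() for t in cell.split(SET_DELIMITER) if t.strip())


def read_reactions(path: str | Path) -> list[ReactionRecord]:
    """Read a reaction table (reaction_id, genes, reactants, products).

    Set-valued cells are ";"-delimited; an empty genes cell is a spontaneous
    reaction. Empty reactants or products are format errors.
    """
    records = []
    for i, row in _read_rows(path, ("reaction_id", "genes", "reactants", "products")):
        reactants = _parse_set(row["reactants"])
        products = _parse_set(row["products"])
        if not reactants or not products:
            raise FormatError(f"{path}: row {i}: empty reactants or products")
        records.append(
            ReactionRecord(
                reaction_id=row["reaction_id"].strip(),
                genes=_parse_set(row["genes"]),
                reactants=reactants,
                products=products,
            )
        )
    return records


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read gene -> localization term pairs; exact duplicate rows collapse."""
    records: list[AnnotationRecord] = []
    seen: set[AnnotationRecord] = set()
    duplicates = 0
    for i, row in _read_rows(path, ("gene", "term")):
        gene, term = row["gene"].strip(), row["term"].strip()
        if not gene:
            raise FormatError(f"{path}: row {i}: empty gene")
        if not term:
            raise FormatError(f"{path}: row {i}: empty term")
        rec = AnnotationRecord(gene, term)
        if rec in seen:
            duplicates += 1
        else:
            seen.add(rec)
            records.append(rec)
    if duplicates:
        logger.info("read_annotations(%s): collapsed %d duplicate rows", path, duplicates)
    return records


def read_expression(path: str | Path, n_tissues: int = 32) -> list[ExpressionProfile]:
    """Read a gene x tissue tpm matrix with exactly ``n_tissues`` value columns."""
    path = Path(path)
    profiles = []
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if not header or header[0] != "gene":
            raise FormatError(f"{path}: first column must be 'gene'")
        if len(header) - 1 != n_tissues:
            raise FormatError(
                f"{path}: expected {n_tissues} tissue columns, found {len(header) - 1}"
            )
        for i, row in enumerate(reader, start=1):
            if len(row) != n_tissues + 1:
                raise FormatError(f"{path}: row {i}: wrong column count")
            try:
                values = tuple(float(v) for v in row[1:])
            except ValueError as exc:
                raise FormatError(f"{path}: row {i}: non-numeric tpm value") from exc
            if any(v < 0 for v in values):
                raise FormatError(f"{path}: row {i}: negative tpm value")
            profiles.append(ExpressionProfile(row[0].strip(), values))
    return profiles


def read_gene_list(path: str | Path) -> list[str]:
    """Read a label list: one gene identifier per line, order kept, dups collapsed."""
    genes: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        gene = line.strip()
        if gene and gene not in seen:
            seen.add(gene)
            genes.append(gene)
    return genes


SCORE_COLUMNS = (
    "gene",
    "normal_median",
    "normal_min",
    "normal_max",
    "shuffled_median",
    "shuffled_min",
    "shuffled_max",
    "N",
    "W",
    "significant",
)


def write_scores(table, path: str | Path) -> None:
    """Write a per-gene score table (``GeneScoreTable``) to TSV.

    Rows are sorted by normal median descending, ties broken by gene id
    ascending; ``W`` is empty for the N=0 sentinel.
    """
    rows = sorted(table.rows, key=lambda r: (-r.normal_median, r.gene))
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(SCORE_COLUMNS)
        for r in rows:
            w = "" if r.wilcoxon.W is None else repr(float(r.wilcoxon.W))
            writer.writerow(
                [
                    r.gene,
                    repr(float(r.normal_median)),
                    repr(float(r.normal_min)),
                    repr(float(r.normal_max)),
                    repr(float(r.shuffled_median)),
                    repr(float(r.shuffled_min)),
                    repr(float(r.shuffled_max)),
                    r.wilcoxon.N,
                    w,
                    int(r.wilcoxon.significant),
                ]
            )


def read_scores(path: str | Path):
    """Round-trip reader for :func:`write_scores` output."""
    from .learning import GeneScore, GeneScoreTable, WilcoxonResult

    rows = []
    for _, row in _read_rows(path, SCORE_COLUMNS):
        w = float(row["W"]) if row["W"] != "" else None
        rows.append(
            GeneScore(
                gene=row["gene"],
                normal_scores=(),
                shuffled_scores=(),
                normal_median=float(row["normal_median"]),
                normal_min=float(row["normal_min"]),
                normal_max=float(row["normal_max"]),
                shuffled_median=float(row["shuffled_median"]),
                shuffled_min=float(row["shuffled_min"]),
                shuffled_max=float(row["shuffled_max"]),
                wilcoxon=WilcoxonResult(
                    W=w,
                    N=int(row["N"]),
                    W_c=None,
                    significant=bool(int(row["significant"])),
                    exact_p=None,
                ),
            )
        )
    return GeneScoreTable(rows=rows)
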