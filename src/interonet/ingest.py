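"""Readers and writers for the five plain-text input dialects.

* accession lists: one accession per line, ``#`` comments allowed;
* reference interactions: tab-separated MITAB-like table with accession,
  taxid and interaction-type columns (other columns kept as provenance);
* homology hits: BLAST tabular (outfmt-6-like), 12 columns, no header,
  E-value in column 11;
* yeast-two-hybrid clone tables: prey accession, clone count, in-frame
  flag, optional exclusion reason;
* gold networks: pair rows (isolated proteins carry an empty partner).

Each loader applies the corresponding filter rule (annotation-set
membership, the global E-value cutoff, in-frame/exclusion dropping,
unordered deduplication), so re-loading a loader's own output is a
no-op.  The writers emit exactly the dialect the loaders read.
"""

from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path
from typing import List, Optional, Union

import pandas as pd

from .expression import ExpressionMatrix
from .types import (
    AnnotatedProteinSet,
    GoldNetwork,
    HomologyHit,
    HomologyTable,
    ReferenceInteraction,
    ReferenceInteractome,
    Y2HRecord,
    unordered,
)

__all__ = [
    "load_protein_set",
    "load_reference_interactions",
    "load_homology_hits",
    "load_y2h_table",
    "load_gold_network",
    "load_expression_matrix",
    "write_protein_set",
    "write_reference_interactions",
    "write_homology_hits",
    "write_y2h_table",
    "write_gold_network",
    "write_expression_matrix",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: default E-value cutoff applied when loading homology hits
DEFAULT_E_CUTOFF = 1e-4

_MITAB_COLUMNS = ["acc_a", "acc_b", "taxid_a", "taxid_b",
                  "interaction_type", "provenance"]


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def load_protein_set(
    path: PathLike,
    species_taxid: int,
    annotation: str = "autophagy",
) -> AnnotatedProteinSet:
    """Read an accession list (one per line; ``#`` comments skipped).

    Duplicates raise a warning and are removed; an empty file is an
    error.
    """
    accessions: List[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        accessions.append(line)
    unique = set(accessions)
    if not unique:
        raise ValueError(f"no accessions in {path}")
    if len(unique) < len(accessions):
        warnings.warn(f"{len(accessions) - len(unique)} duplicate "
                      f"accessions in {path}; deduplicated")
    logger.info("loaded %d accessions from %s", len(unique), path)
    return AnnotatedProteinSet(species_taxid=species_taxid,
                               accessions=frozenset(unique),
                               annotation=annotation)


def load_reference_interactions(
    path: PathLike,
    protein_set: AnnotatedProteinSet,
    include_self: bool = False,
) -> ReferenceInteractome:
    """Read a MITAB-like interaction table, keeping in-set interactions.

    Only interactions with *both* endpoints inside ``protein_set`` are
    retained; pairs are deduplicated without regard to orientation.
    Self-interactions are excluded unless ``include_self``.  Malformed
    rows are skipped with a warning.
    """
    taxid = protein_set.species_taxid
    interactions: List[ReferenceInteraction] = []
    seen = set()
    n_rows = 0
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            n_rows += 1
            try:
                a = row["acc_a"].strip()
                b = row["acc_b"].strip()
                itype = (row.get("interaction_type") or "").strip()
                prov = (row.get("provenance") or "").strip()
                if not a or not b:
                    raise KeyError("empty accession")
            except (KeyError, AttributeError) as exc:
                warnings.warn(f"skipping malformed interaction row "
                              f"{n_rows}: {exc}")
                continue
            if a == b and not include_self:
                continue
            if a not in protein_set or b not in protein_set:
                continue
            pair = unordered(a, b)
            if pair in seen:
                continue
            seen.add(pair)
            interactions.append(
                ReferenceInteraction(a, b, taxid,
                                     interaction_type=itype or "physical",
                                     provenance=prov))
    if not interactions:
        warnings.warn(f"no interactions retained from {path}")
    logger.info("retained %d of %d interaction rows from %s",
                len(interactions), n_rows, path)
    return ReferenceInteractome(protein_set=protein_set,
                                interactions=interactions)


def load_homology_hits(
    path: PathLike,
    subject_taxid: int,
    e_cutoff: float = DEFAULT_E_CUTOFF,
) -> HomologyTable:
    """Read BLAST tabular output (outfmt 6), applying the E-value cutoff.

    Expects at least 12 tab-separated columns with query in column 1,
    subject in column 2 and E-value in column 11.  Hits above the cutoff
    are dropped; duplicate (query, subject) pairs collapse to the
    minimum E-value; unparseable E-values are skipped with a warning.
    """
    hits: List[HomologyHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                warnings.warn(f"skipping short row {lineno} in {path}")
                continue
            try:
                evalue = float(fields[10])
                if evalue < 0:
                    raise ValueError("negative E-value")
            except ValueError:
                warnings.warn(
                    f"skipping row {lineno} in {path}: unparseable "
                    f"E-value {fields[10]!r}")
                continue
            if evalue > e_cutoff:
                continue
            hits.append(HomologyHit(query=fields[0], subject=fields[1],
                                    evalue=evalue,
                                    subject_taxid=subject_taxid))
    table = HomologyTable(hits)
    logger.info("loaded %d homology hits (cutoff %.0e) from %s",
                len(table), e_cutoff, path)
    return table


def load_y2h_table(path: PathLike) -> List[Y2HRecord]:
    """Read a clone-level yeast-two-hybrid table and aggregate per prey.

    Rows that are out of frame or carry a non-empty exclusion reason are
    dropped; the clone counts of the remaining rows are summed per prey
    accession.  A missing clone count defaults to 1 with a warning.
    """
    counts: dict = {}
    order: List[str] = []
    n_dropped = 0
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            prey = (row.get("prey_accession") or "").strip()
            if not prey:
                warnings.warn("skipping row without prey accession")
                continue
            raw_count = (row.get("clone_count") or "").strip()
            if not raw_count:
                warnings.warn(f"missing clone count for {prey}; "
                              "defaulting to 1")
                count = 1
            else:
                count = int(raw_count)
            in_frame = (row.get("in_frame") or "true").strip().lower() in (
                "true", "1", "yes")
            reason = (row.get("excluded_reason") or "").strip()
            if not in_frame or reason:
                n_dropped += 1
                continue
            if prey not in counts:
                counts[prey] = 0
                order.append(prey)
            counts[prey] += count
    if not counts:
        warnings.warn(f"no retained yeast-two-hybrid records in {path}")
    logger.info("retained %d preys (%d clone rows dropped) from %s",
                len(counts), n_dropped, path)
    return [Y2HRecord(prey_accession=p, clone_count=counts[p])
            for p in sorted(order)]


def load_gold_network(path: PathLike) -> GoldNetwork:
    """Read a gold network table (pair rows; empty partner = isolated)."""
    proteins = set()
    pairs = set()
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            a = (row.get("acc_a") or "").strip()
            b = (row.get("acc_b") or "").strip()
            if not a:
                continue
            proteins.add(a)
            if b:
                proteins.add(b)
                pairs.add(unordered(a, b))
    if not proteins:
        raise ValueError(f"empty gold network in {path}")
    return GoldNetwork(proteins=frozenset(proteins),
                       interactions=frozenset(pairs))


def load_expression_matrix(
    path: PathLike, age_points=None
) -> ExpressionMatrix:
    """Read a genes x age-points TSV (gene id column + one column per age)."""
    frame = pd.read_csv(path, sep="\t", index_col=0,
                        float_precision="round_trip")
    return ExpressionMatrix(values=frame, age_points=age_points)


# ---------------------------------------------------------------------------
# writers (the exact dialects the loaders read)
# ---------------------------------------------------------------------------

def write_protein_set(path: PathLike, protein_set: AnnotatedProteinSet) -> None:
    lines = [f"# taxid={protein_set.species_taxid} "
             f"annotation={protein_set.annotation}"]
    lines.extend(sorted(protein_set.accessions))
    Path(path).write_text("\n".join(lines) + "\n")


def write_reference_interactions(
    path: PathLike, interactome: ReferenceInteractome
) -> None:
    taxid = interactome.species_taxid
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_MITAB_COLUMNS)
        for ia in sorted(interactome.interactions, key=lambda i: i.pair):
            writer.writerow([ia.a, ia.b, taxid, taxid,
                             ia.interaction_type, ia.provenance])


def write_homology_hits(
    path: PathLike,
    table: HomologyTable,
    subject_taxid: Optional[int] = None,
) -> None:
    """Write BLAST outfmt-6-like rows (optionally one species only).

    Alignment-detail columns are synthetic placeholders; query, subject
    and E-value round-trip exactly.
    """
    with open(path, "w", newline="") as handle:
        for hit in sorted(table, key=lambda h: (h.query, h.subject)):
            if subject_taxid is not None and hit.subject_taxid != subject_taxid:
                continue
            handle.write("\t".join([
                hit.query, hit.subject, "50.0", "100", "0", "0",
                "1", "100", "1", "100", f"{hit.evalue:.17g}", "200.0",
            ]) + "\n")


def write_y2h_table(path: PathLike, rows: pd.DataFrame) -> None:
    rows.to_csv(path, sep="\t", index=False)


def write_gold_network(path: PathLike, gold: GoldNetwork) -> None:
    linked = {p for pair in gold.interactions for p in pair}
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["acc_a", "acc_b"])
        for a, b in sorted(gold.interactions):
            writer.writerow([a, b])
        for p in sorted(gold.proteins - linked):
            writer.writerow([p, ""])


def write_expression_matrix(path: PathLike, expr: ExpressionMatrix) -> None:
    expr.values.to_csv(path, sep="\t", index=True, float_format="%.17g")
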