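"""Data model and readers for dual-gene multiplex amplicon panels.

A panel is a set of PCR *plexes* (multiplex reactions), each amplifying a
subset of the panel's amplicons.  Every amplicon belongs to exactly one of
two gene labels (``BRCA1``/``BRCA2`` in the bundled default) and carries an
expected capillary-electrophoresis fragment length.  Cross-gene
normalization -- each gene acting as the copy-number reference for the
other -- requires every plex to contain at least one amplicon of each
gene; this is enforced as a panel invariant.

Coordinate convention
---------------------
Genomic intervals are stored 1-based and :func:`genomic_span` returns
``end - start`` (NOT ``end - start + 1``).  This matches the arithmetic
used in clinical LGR reports of the form "a deletion of N base pairs
ranging from chrX:start to chrX:end", where N = end - start.  BED export
converts to 0-based half-open coordinates.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class GenomicInterval(BaseModel):
    """A 1-based genomic interval with ``end >= start``."""

    model_config = ConfigDict(frozen=True)

    chrom: str = Field(min_length=1)
    start: int = Field(ge=1)
    end: int = Field(ge=1)

    @model_validator(mode="after")
    def _check_order(self) -> "GenomicInterval":
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        return self


def genomic_span(iv: GenomicInterval) -> int:
    """Span of an interval in bp, defined as ``end - start``.

    The convention follows the clinical reporting arithmetic for large
    genomic rearrangements (e.g. chr17:41256109-41258773 is a "2664 bp"
    deletion: 41258773 - 41256109 = 2664).
    """
    return iv.end - iv.start


class AmpliconDef(BaseModel):
    """One amplicon of the panel.

    ``id`` is a plex-scoped opaque label (e.g. ``"D_9"``, ``"A_6a"``); an
    optional suffix letter distinguishes split amplicons and is never
    parsed.
    """

    model_config = ConfigDict(frozen=True)

    id: str = Field(min_length=1)
    plex_id: str = Field(min_length=1)
    gene: str = Field(min_length=1)
    expected_length_bp: float = Field(gt=0)
    interval: Optional[GenomicInterval] = None
    exon_label: Optional[str] = None


class PanelDesign(BaseModel):
    """The full multiplex amplicon layout of a dual-gene panel."""

    model_config = ConfigDict(frozen=True)

    gene_labels: tuple[str, str]
    plexes: tuple[str, ...]
    amplicons: tuple[AmpliconDef, ...]

    @model_validator(mode="after")
    def _check_invariants(self) -> "PanelDesign":
        g1, g2 = self.gene_labels
        if g1 == g2:
            raise ValueError("the two gene labels must differ")
        if not self.amplicons:
            raise ValueError("panel defines zero amplicons")
        seen: set[str] = set()
        for amp in self.amplicons:
            if amp.id in seen:
                raise ValueError(f"duplicate amplicon id {amp.id!r}")
            seen.add(amp.id)
            if amp.gene not in self.gene_labels:
                raise ValueError(
                    f"amplicon {amp.id!r}: unknown gene label {amp.gene!r} "
                    f"(panel genes: {g1!r}, {g2!r})"
                )
            if amp.plex_id not in self.plexes:
                raise ValueError(
                    f"amplicon {amp.id!r}: unknown plex {amp.plex_id!r}"
                )
        for plex in self.plexes:
            genes = {a.gene for a in self.amplicons if a.plex_id == plex}
            if not genes:
                raise ValueError(f"plex {plex!r} has no amplicons")
            missing = set(self.gene_labels) - genes
            if missing:
                raise ValueError(
                    f"plex {plex!r} lacks amplicons of gene "
                    f"{sorted(missing)[0]!r}; cross-gene normalization needs "
                    "both genes in every plex"
                )
        return self

    # -- convenience accessors -------------------------------------------

    def amplicons_in_plex(self, plex_id: str) -> tuple[AmpliconDef, ...]:
        return tuple(a for a in self.amplicons if a.plex_id == plex_id)

    def amplicons_for_gene(
        self, gene: str, plex_id: str | None = None
    ) -> tuple[AmpliconDef, ...]:
        return tuple(
            a
            for a in self.amplicons
            if a.gene == gene and (plex_id is None or a.plex_id == plex_id)
        )

    def by_id(self, amplicon_id: str) -> AmpliconDef:
        for a in self.amplicons:
            if a.id == amplicon_id:
                return a
        raise KeyError(amplicon_id)

    def other_gene(self, gene: str) -> str:
        """The cross-normalization partner of ``gene``."""
        g1, g2 = self.gene_labels
        if gene == g1:
            return g2
        if gene == g2:
            return g1
        raise ValueError(f"unknown gene label {gene!r}")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "gene_labels": list(self.gene_labels),
            "plexes": list(self.plexes),
            "amplicons": [
                {
                    k: v
                    for k, v in {
                        "id": a.id,
                        "plex_id": a.plex_id,
                        "gene": a.gene,
                        "expected_length_bp": a.expected_length_bp,
                        "interval": (
                            a.interval.model_dump() if a.interval else None
                        ),
                        "exon_label": a.exon_label,
                    }.items()
                    if v is not None
                }
                for a in self.amplicons
            ],
        }

    def save(self, path: str | Path) -> None:
        """Serialize to the YAML panel-config schema read by :func:`load_panel`."""
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )


def load_panel(path: str | Path) -> PanelDesign:
    """Load and validate a panel config file.

    Schema (YAML)::

        gene_labels: [BRCA1, BRCA2]
        plexes: [A, B, C, D, E]
        amplicons:
          - id: A_1
            plex_id: A
            gene: BRCA2
            expected_length_bp: 160
            interval: {chrom: chr13, start: 32890598, end: 32890750}   # optional
            exon_label: "BRCA2 ex2"                                    # optional

    Raises a validation error for duplicate ids, unknown gene labels, or a
    plex lacking one of the two genes.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ValueError(f"panel config {path}: expected a mapping at top level")
    return PanelDesign.model_validate(raw)


def default_panel() -> PanelDesign:
    """The bundled default dual-gene panel.

    93 amplicons over 5 plexes (A:17, B:20, C:19, D:18, E:19) covering
    BRCA1 (41 amplicons) and BRCA2 (52 amplicons).  Amplicon ids follow
    the ``<plex>_<index>`` grammar with the split pair ``A_6a``/``A_6b``.
    Expected sizes and genomic intervals are synthetic placeholders laid
    out to be realistic for a capillary-electrophoresis multiplex design
    (within-plex spacing >= 4 bp, sizes within the 600-bp ladder range);
    replace the config file to describe a real kit.
    """
    with resources.files("ampcnv.data").joinpath("default_panel.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        return PanelDesign.model_validate(yaml.safe_load(fh))


def write_bed(panel: PanelDesign, path: str | Path) -> int:
    """Write amplicon intervals as BED (0-based half-open).

    Amplicons without intervals are skipped.  Returns the number of
    records written.
    """
    lines = []
    for a in panel.amplicons:
        if a.interval is None:
            continue
        lines.append(
            f"{a.interval.chrom}\t{a.interval.start - 1}\t{a.interval.end}"
            f"\t{a.id}\t0\t.\n"
        )
    Path(path).write_text("".join(lines), encoding="utf-8")
    return len(lines)


def iter_plex_ids(panel: PanelDesign) -> Iterable[str]:
    return panel.plexes
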