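"""Dosage quotient (DQ) / relative peak ratio (RPR) computation.

MAQ (multiplex amplicon quantification) and MLPA (multiplex
ligation-dependent probe amplification) both quantify per-target copy
number from capillary-electrophoresis peak heights via the same double
normalization:

1. within each sample, divide every probe height by the median height of
   that sample's REFERENCE probes (probes in regions assumed two-copy);
2. divide the test sample's normalized value by the median of the control
   samples' normalized values, probe by probe.

Under the proportional model ``height ∝ copy number``, the resulting
dosage quotient equals CN/2 for diploid controls: ~1.0 normal, ~0.5
heterozygous deletion, ~1.5 heterozygous duplication, 0 homozygous
deletion (an absent peak is a dq of 0, not an error).  Values are gated
against the normal range 0.7-1.3.  MAQ and MLPA runs differ only in
their probe panels; the computation is shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Literal, Optional

import numpy as np
import pandas as pd
import yaml
from matplotlib.figure import Figure
from pydantic import BaseModel, ConfigDict, Field, model_validator

from ampcnv.states import DosageClass, GeneState

DEFAULT_LOW = 0.7
DEFAULT_HIGH = 1.3


class ProbeDef(BaseModel):
    """One MAQ/MLPA probe: a gene-targeted or copy-number-reference probe."""

    model_config = ConfigDict(frozen=True)

    id: str = Field(min_length=1)
    role: Literal["TARGET", "REFERENCE"]
    gene: Optional[str] = None
    exon_label: Optional[str] = None
    expected_length_bp: float = Field(gt=0)

    @model_validator(mode="after")
    def _check_gene(self) -> "ProbeDef":
        if self.role == "TARGET" and not self.gene:
            raise ValueError(f"TARGET probe {self.id!r} needs a gene label")
        return self


class ProbePanel(BaseModel):
    """A probe set with at least two REFERENCE probes."""

    model_config = ConfigDict(frozen=True)

    name: str
    gene_labels: tuple[str, ...]
    probes: tuple[ProbeDef, ...]

    @model_validator(mode="after")
    def _check(self) -> "ProbePanel":
        ids = [p.id for p in self.probes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate probe ids")
        n_ref = sum(1 for p in self.probes if p.role == "REFERENCE")
        if n_ref < 2:
            raise ValueError(f"probe panel needs >= 2 REFERENCE probes, has {n_ref}")
        for p in self.probes:
            if p.gene is not None and p.gene not in self.gene_labels:
                raise ValueError(f"probe {p.id!r}: unknown gene {p.gene!r}")
        return self

    def targets(self, gene: str | None = None) -> tuple[ProbeDef, ...]:
        return tuple(
            p
            for p in self.probes
            if p.role == "TARGET" and (gene is None or p.gene == gene)
        )

    def references(self) -> tuple[ProbeDef, ...]:
        return tuple(p for p in self.probes if p.role == "REFERENCE")


def _load_bundled(name: str) -> ProbePanel:
    with resources.files("ampcnv.data").joinpath(name).open(
        "r", encoding="utf-8"
    ) as fh:
        return ProbePanel.model_validate(yaml.safe_load(fh))


def default_maq_panel() -> ProbePanel:
    """Bundled MAQ-style probe panel (synthetic layout)."""
    return _load_bundled("maq_probes.yaml")


def default_mlpa_panel() -> ProbePanel:
    """Bundled MLPA-style per-exon probe panel (synthetic layout)."""
    return _load_bundled("mlpa_probes.yaml")


def load_probe_panel(path: str | Path) -> ProbePanel:
    return ProbePanel.model_validate(
        yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    )


@dataclass
class DosageRun:
    """One test sample plus >= 3 control samples' peak heights per probe.

    A probe absent from the test sample's heights models a homozygous
    deletion (no peak); reference probes must be present and positive in
    every sample.
    """

    panel: ProbePanel
    test: dict[str, float]                 # probe_id -> height
    controls: dict[str, dict[str, float]]  # sample -> probe_id -> height
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.controls) < 3:
            raise ValueError(
                f"need >= 3 control samples, have {len(self.controls)}"
            )
        ref_ids = [p.id for p in self.panel.references()]
        for name, heights in [("test", self.test)] + list(self.controls.items()):
            for rid in ref_ids:
                if heights.get(rid, 0.0) <= 0:
                    raise ValueError(
                        f"sample {name!r}: reference probe {rid!r} height "
                        "missing or non-positive"
                    )
        for name, heights in self.controls.items():
            for p in self.panel.probes:
                if heights.get(p.id, 0.0) <= 0:
                    raise ValueError(
                        f"control {name!r}: probe {p.id!r} height missing "
                        "or non-positive"
                    )


@dataclass
class DosageResult:
    """Per-target-probe dosage quotients with optional classification."""

    panel: ProbePanel
    dq: dict[str, float]                       # target probe_id -> dq
    classification: dict[str, DosageClass] = field(default_factory=dict)
    gene_summary: dict[str, GeneState] = field(default_factory=dict)
    normal_range: tuple[float, float] | None = None

    def gene_dq(self, gene: str) -> dict[str, float]:
        return {p.id: self.dq[p.id] for p in self.panel.targets(gene)}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.panel.targets():
            rows.append(
                {
                    "probe_id": p.id,
                    "gene": p.gene,
                    "exon_label": p.exon_label,
                    "dq": self.dq[p.id],
                    "classification": (
                        self.classification[p.id].value
                        if p.id in self.classification
                        else ""
                    ),
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "panel": self.panel.name,
            "dq": {k: round(v, 6) for k, v in self.dq.items()},
            "classification": {
                k: v.value for k, v in self.classification.items()
            },
            "gene_summary": {k: v.value for k, v in self.gene_summary.items()},
            "normal_range": list(self.normal_range) if self.normal_range else None,
        }

    @classmethod
    def from_json_dict(cls, d: dict, panel: ProbePanel) -> "DosageResult":
        if panel.name != d.get("panel"):
            raise ValueError(
                f"probe panel {panel.name!r} does not match result "
                f"({d.get('panel')!r})"
            )
        return cls(
            panel=panel,
            dq=dict(d["dq"]),
            classification={
                k: DosageClass(v) for k, v in d["classification"].items()
            },
            gene_summary={
                k: GeneState(v) for k, v in d["gene_summary"].items()
            },
            normal_range=(
                tuple(d["normal_range"]) if d.get("normal_range") else None
            ),
        )


def compute_dq(
    run: DosageRun,
    center: Callable[[np.ndarray], float] = np.median,
) -> DosageResult:
    """Doubly normalized dosage quotient for every TARGET probe.

    v(s, p) = height(s, p) / center over REFERENCE probes r of height(s, r)
    dq(p)   = v(test, p) / center over controls c of v(c, p)

    ``center`` defaults to the median (robust to a CNV within the
    reference set or an outlier control); pass ``np.mean`` to mimic
    mean-based software.  A target probe with no peak in the test sample
    yields dq 0.
    """
    ref_ids = [p.id for p in run.panel.references()]

    def normalized(heights: dict[str, float], pid: str) -> float:
        ref = float(center(np.array([heights[r] for r in ref_ids], dtype=float)))
        return heights.get(pid, 0.0) / ref

    dq: dict[str, float] = {}
    for p in run.panel.targets():
        v_test = normalized(run.test, p.id)
        v_controls = np.array(
            [normalized(h, p.id) for h in run.controls.values()], dtype=float
        )
        dq[p.id] = v_test / float(center(v_controls))
    return DosageResult(panel=run.panel, dq=dq)


def classify_dq(
    result: DosageResult,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
) -> DosageResult:
    """Classify each dq against the closed normal range [low, high].

    dq < low -> DELETED; dq > high -> DUPLICATED; otherwise NORMAL.  The
    per-gene summary is WHOLE_LOSS/WHOLE_GAIN when *all* of a gene's
    probes are DELETED/DUPLICATED, PARTIAL_* when only some are, NEUTRAL
    when none.
    """
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    classification: dict[str, DosageClass] = {}
    for pid, v in result.dq.items():
        if v < low:
            classification[pid] = DosageClass.DELETED
        elif v > high:
            classification[pid] = DosageClass.DUPLICATED
        else:
            classification[pid] = DosageClass.NORMAL

    gene_summary: dict[str, GeneState] = {}
    for gene in result.panel.gene_labels:
        probes = result.panel.targets(gene)
        if not probes:
            continue
        states = [classification[p.id] for p in probes]
        n_del = states.count(DosageClass.DELETED)
        n_dup = states.count(DosageClass.DUPLICATED)
        if n_del == len(states):
            gene_summary[gene] = GeneState.WHOLE_LOSS
        elif n_dup == len(states):
            gene_summary[gene] = GeneState.WHOLE_GAIN
        elif n_del and n_del >= n_dup:
            gene_summary[gene] = GeneState.PARTIAL_LOSS
        elif n_dup:
            gene_summary[gene] = GeneState.PARTIAL_GAIN
        else:
            gene_summary[gene] = GeneState.NEUTRAL
    return DosageResult(
        panel=result.panel,
        dq=result.dq,
        classification=classification,
        gene_summary=gene_summary,
        normal_range=(low, high),
    )


def read_peak_table(
    path: str | Path, panel: ProbePanel, test_sample: str
) -> DosageRun:
    """Build a :class:`DosageRun` from a tidy peak table.

    Expected columns: ``sample``, ``probe_id``, ``height``; every sample
    other than ``test_sample`` is treated as a control.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "probe_id", "height"}
    if not required.issubset(df.columns):
        raise ValueError(f"peak table {path} must have columns {sorted(required)}")
    by_sample = {
        str(s): dict(zip(sub["probe_id"], sub["height"].astype(float)))
        for s, sub in df.groupby("sample", sort=False)
    }
    if test_sample not in by_sample:
        raise ValueError(f"test sample {test_sample!r} not in peak table")
    test = by_sample.pop(test_sample)
    return DosageRun(panel=panel, test=test, controls=by_sample)


def write_peak_table(run: DosageRun, path: str | Path, test_sample: str = "TEST") -> None:
    rows = []
    for pid, h in run.test.items():
        rows.append({"sample": test_sample, "probe_id": pid, "height": h})
    for sample, heights in run.controls.items():
        for pid, h in heights.items():
            rows.append({"sample": sample, "probe_id": pid, "height": h})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def plot_dq(
    result: DosageResult, out_path: str | Path,
    low: float = DEFAULT_LOW, high: float = DEFAULT_HIGH,
) -> None:
    """Per-probe dosage plot with the normal-range band."""
    df = result.to_frame()
    fig = Figure(figsize=(max(6, 0.18 * len(df)), 4))
    ax = fig.add_subplot(111)
    ax.axhspan(low, high, color="tab:blue", alpha=0.15, label=f"normal {low}-{high}")
    colors = {g: c for g, c in zip(result.panel.gene_labels,
                                   ["tab:red", "tab:green", "tab:purple"])}
    for gene, sub in df.groupby("gene"):
        ax.plot(sub.index, sub["dq"], "o", ms=4,
                color=colors.get(gene, "gray"), label=gene)
    ax.axhline(1.0, color="k", lw=0.5, ls="--")
    ax.set_xticks(df.index)
    ax.set_xticklabels(df["probe_id"], rotation=90, fontsize=5)
    ax.set_ylabel("dosage quotient")
    ax.set_ylim(0, max(2.0, float(df["dq"].max()) * 1.15))
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
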