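"""Cross-gene normalization of fragment-analysis peak heights.

Amplicon-based panels carry no absolute copy-number anchor: every peak
height is proportional to input amount, injection and amplification
efficiency.  The workaround is *intra-sample cross-gene normalization*
against a "true negative" (TN-CNV) reference profile -- a sample (or
pool) previously confirmed copy-number-normal by an orthogonal dosage
assay:

* anchor on gene 1: scale the sample so that gene-1 amplicons match the
  reference (median of reference/sample height ratios over gene-1
  amplicons), then read off each amplicon's ratio;
* repeat anchored on gene 2.

A heterozygous deletion shows up as ratios near 0.5 on the affected
amplicons.  The construction has a built-in identifiability limit: a
whole-gene deletion of one gene and a whole-gene duplication of the
other produce the *same* pair of normalized profiles (ratios r vs 1/r),
which is why gene-level resolution is deferred to dosage evidence
(:mod:`ampcnv.dosage`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from matplotlib.figure import Figure

from ampcnv.fragtrace import BP, CalibratedPeakSet, CalibrationFit, RawTrace
from ampcnv.panel import PanelDesign
from ampcnv.states import FaFlag

#: Default ratio gate: the dosage-assay normal range, reused for FA ratios.
DEFAULT_LOW = 0.7
DEFAULT_HIGH = 1.3


@dataclass
class ReferenceProfile:
    """The TN-CNV (true-negative) reference: one calibrated peak set per plex.

    The reference must cover every amplicon of the panel -- a reference
    with dropouts cannot anchor normalization.
    """

    peaksets: dict[str, CalibratedPeakSet]
    provenance: str = "TN-CNV reference"

    @classmethod
    def from_peaksets(
        cls,
        panel: PanelDesign,
        peaksets: dict[str, CalibratedPeakSet],
        provenance: str = "TN-CNV reference",
    ) -> "ReferenceProfile":
        for plex in panel.plexes:
            if plex not in peaksets:
                raise ValueError(f"reference profile missing plex {plex!r}")
            missing = peaksets[plex].missing_ids()
            if missing:
                raise ValueError(
                    f"reference profile has MISSING amplicons in plex "
                    f"{plex!r}: {missing}"
                )
        return cls(peaksets=peaksets, provenance=provenance)

    @classmethod
    def from_pool(
        cls,
        panel: PanelDesign,
        profiles: list[dict[str, CalibratedPeakSet]],
        provenance: str = "pooled TN-CNV reference",
    ) -> "ReferenceProfile":
        """Pool several confirmed-normal samples by per-amplicon median height."""
        if not profiles:
            raise ValueError("need >= 1 profile to pool")
        from ampcnv.fragtrace import Peak

        pooled: dict[str, CalibratedPeakSet] = {}
        for plex in panel.plexes:
            amps = panel.amplicons_in_plex(plex)
            assignments = {}
            for a in amps:
                heights, positions = [], []
                for prof in profiles:
                    peak = prof[plex].assignments.get(a.id)
                    if peak is not None:
                        heights.append(peak.height)
                        positions.append(peak.position)
                if not heights:
                    raise ValueError(
                        f"no pooled sample carries amplicon {a.id!r}"
                    )
                assignments[a.id] = Peak(
                    position=float(np.median(positions)),
                    height=float(np.median(heights)),
                    unit=BP,
                )
            pooled[plex] = CalibratedPeakSet(
                sample_id="POOLED_TN",
                plex_id=plex,
                peaks=list(assignments.values()),
                assignments=assignments,
            )
        return cls.from_peaksets(panel, pooled, provenance=provenance)


@dataclass
class NormalizedProfile:
    """Per-amplicon sample/reference height ratios under one anchor gene."""

    plex_id: str
    ref_gene: str
    scale: float
    ratios: dict[str, Optional[float]]
    flags: dict[str, FaFlag] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "amplicon_id": list(self.ratios),
                "ratio": [
                    np.nan if r is None else r for r in self.ratios.values()
                ],
                "flag": [
                    self.flags.get(a, FaFlag.MISSING).value for a in self.ratios
                ],
            }
        )


def normalize_by_reference_gene(
    sample: CalibratedPeakSet,
    reference: ReferenceProfile,
    panel: PanelDesign,
    ref_gene: str,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
) -> NormalizedProfile:
    """Normalize sample peak heights against the reference, anchored on
    ``ref_gene``.

    scale  = median over ref_gene amplicons of (reference_height / sample_height)
    ratio_a = scale * sample_height_a / reference_height_a

    Anchor-gene amplicons therefore center on 1.0 by construction; the
    median anchor is robust to a minority of CNV-affected amplicons
    within the anchor gene.  Raises when every anchor amplicon is missing
    from the sample.
    """
    if ref_gene not in panel.gene_labels:
        raise ValueError(f"unknown reference gene {ref_gene!r}")
    plex = sample.plex_id
    ref_ps = reference.peaksets[plex]

    anchor_ratios = []
    for a in panel.amplicons_for_gene(ref_gene, plex_id=plex):
        hs = sample.height(a.id)
        hr = ref_ps.height(a.id)
        if hs is not None and hr is not None:
            anchor_ratios.append(hr / hs)
    if not anchor_ratios:
        raise ValueError(
            f"no normalization anchor: all {ref_gene} amplicons MISSING in "
            f"sample {sample.sample_id!r} plex {plex!r}"
        )
    scale = float(np.median(anchor_ratios))

    ratios: dict[str, Optional[float]] = {}
    for a in panel.amplicons_in_plex(plex):
        hs = sample.height(a.id)
        hr = ref_ps.height(a.id)
        ratios[a.id] = None if hs is None else scale * hs / hr
    profile = NormalizedProfile(
        plex_id=plex, ref_gene=ref_gene, scale=scale, ratios=ratios
    )
    profile.flags = collect_out_of_range(profile, low=low, high=high)
    return profile


def collect_out_of_range(
    profile: NormalizedProfile,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
) -> dict[str, FaFlag]:
    """Flag each amplicon's ratio against the closed interval [low, high]."""
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    flags: dict[str, FaFlag] = {}
    for aid, r in profile.ratios.items():
        if r is None:
            flags[aid] = FaFlag.MISSING
        elif r < low:
            flags[aid] = FaFlag.LOW
        elif r > high:
            flags[aid] = FaFlag.HIGH
        else:
            flags[aid] = FaFlag.IN_RANGE
    return flags


@dataclass
class FaReport:
    """Both normalizations for every plex, plus the combined flag table."""

    panel: PanelDesign
    profiles: dict[str, dict[str, NormalizedProfile]]  # plex -> ref_gene -> profile
    low: float = DEFAULT_LOW
    high: float = DEFAULT_HIGH

    def table(self) -> pd.DataFrame:
        g1, g2 = self.panel.gene_labels
        rows = []
        for plex, by_gene in self.profiles.items():
            p1, p2 = by_gene[g1], by_gene[g2]
            for a in self.panel.amplicons_in_plex(plex):
                rows.append(
                    {
                        "plex": plex,
                        "amplicon_id": a.id,
                        "gene": a.gene,
                        f"ratio_ref_{g1}": p1.ratios[a.id],
                        f"flag_ref_{g1}": p1.flags[a.id].value,
                        f"ratio_ref_{g2}": p2.ratios[a.id],
                        f"flag_ref_{g2}": p2.flags[a.id].value,
                    }
                )
        return pd.DataFrame(rows)

    def flags_for(self, amplicon_id: str) -> tuple[FaFlag, FaFlag]:
        """(cross-gene flag, same-gene flag) for one amplicon.

        The *cross* flag comes from the normalization anchored on the
        other gene -- the one sensitive to whole-gene events.
        """
        amp = self.panel.by_id(amplicon_id)
        by_gene = self.profiles[amp.plex_id]
        cross = by_gene[self.panel.other_gene(amp.gene)].flags[amplicon_id]
        same = by_gene[amp.gene].flags[amplicon_id]
        return cross, same

    def to_json_dict(self) -> dict:
        return {
            "gate": {"low": self.low, "high": self.high},
            "plexes": {
                plex: {
                    gene: {
                        "scale": prof.scale,
                        "ratios": prof.ratios,
                        "flags": {k: v.value for k, v in prof.flags.items()},
                    }
                    for gene, prof in by_gene.items()
                }
                for plex, by_gene in self.profiles.items()
            },
        }


def analyze_fa(
    samples: dict[str, CalibratedPeakSet],
    reference: ReferenceProfile,
    panel: PanelDesign,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
) -> FaReport:
    """Run both cross-gene normalizations on every provided plex."""
    profiles: dict[str, dict[str, NormalizedProfile]] = {}
    for plex, peakset in samples.items():
        profiles[plex] = {
            gene: normalize_by_reference_gene(
                peakset, reference, panel, gene, low=low, high=high
            )
            for gene in panel.gene_labels
        }
    return FaReport(panel=panel, profiles=profiles, low=low, high=high)


def overlay_curves(
    sample_trace: RawTrace,
    reference_trace: RawTrace,
    sample_fit: CalibrationFit,
    reference_fit: CalibrationFit,
    panel: PanelDesign,
    plex_id: str,
    channel: str = "sample",
    flags: Optional[dict[str, FaFlag]] = None,
    out_path: str | Path | None = None,
    bp_step: float = 0.25,
) -> pd.DataFrame:
    """Static sample-vs-reference overlay on a common bp axis.

    Sample in red, reference in blue; amplicon expected positions are
    annotated and out-of-range amplicons starred.  Returns the resampled
    aligned curves as a table (bp, sample, reference); writes a plot file
    when ``out_path`` is given.
    """
    if sample_fit is None or reference_fit is None:
        raise ValueError("both traces must be calibrated (fits required)")

    def bp_axis(trace: RawTrace, fit: CalibrationFit) -> tuple[np.ndarray, np.ndarray]:
        y = trace.channels[channel]
        scans = np.arange(len(y))
        return fit.predict(scans), y

    sx, sy = bp_axis(sample_trace, sample_fit)
    rx, ry = bp_axis(reference_trace, reference_fit)
    lo = max(sx.min(), rx.min())
    hi = min(sx.max(), rx.max())
    grid = np.arange(lo, hi, bp_step)
    table = pd.DataFrame(
        {
            "bp": grid,
            "sample": np.interp(grid, sx, sy),
            "reference": np.interp(grid, rx, ry),
        }
    )

    if out_path is not None:
        fig = Figure(figsize=(12, 4))
        ax = fig.add_subplot(111)
        ax.plot(table["bp"], table["reference"], color="tab:blue",
                lw=0.8, label="reference (TN-CNV)")
        ax.plot(table["bp"], table["sample"], color="tab:red",
                lw=0.8, label="sample")
        ymax = float(max(table["sample"].max(), table["reference"].max(), 1.0))
        for a in panel.amplicons_in_plex(plex_id):
            starred = flags is not None and flags.get(a.id) in (
                FaFlag.LOW, FaFlag.HIGH, FaFlag.MISSING,
            )
            label = f"{a.id}*" if starred else a.id
            ax.annotate(
                label,
                xy=(a.expected_length_bp, ymax * 1.02),
                rotation=90, fontsize=6, ha="center", va="bottom",
                color="black" if not starred else "tab:red",
            )
        ax.set_xlabel("size (bp)")
        ax.set_ylabel("fluorescence (a.u.)")
        ax.set_title(f"plex {plex_id}: sample vs TN-CNV reference")
        ax.legend(loc="upper right", fontsize=8)
        ax.set_ylim(0, ymax * 1.25)
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
    return table
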