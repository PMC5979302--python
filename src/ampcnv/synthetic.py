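"""Synthetic fixture generators for every pipeline input.

All generators share one copy-number model: the signal of an amplicon or
probe is proportional to ``efficiency * CN/2``, where CN is the integer
copy number (2 = diploid) and efficiency is a per-amplicon amplification
factor drawn once per cohort (lognormal spread), so that run-level
statistics behave like a real sequencing run.  Observation noise is
multiplicative lognormal -- amplification noise scales with signal.

Every generator takes an explicit seed and records it in its output.
What is *not* modeled: read-level sequencing errors, stutter,
heteroduplex artifacts, dye pull-up, and GC-content efficiency trends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ampcnv.dosage import DosageRun, ProbePanel
from ampcnv.fragtrace import LIZ_600, RawTrace, SizeStandardDef
from ampcnv.panel import PanelDesign
from ampcnv.rc_cnv import ReadCountMatrix


@dataclass(frozen=True)
class CnvSpec:
    """Copy-number assignment: amplicon/probe id -> integer CN (default 2)."""

    states: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for aid, cn in self.states.items():
            if not isinstance(cn, (int, np.integer)) or cn < 0:
                raise ValueError(f"copy number for {aid!r} must be an int >= 0")

    def cn(self, item_id: str) -> int:
        return self.states.get(item_id, 2)

    @classmethod
    def diploid(cls) -> "CnvSpec":
        return cls()

    @classmethod
    def whole_gene(cls, panel_or_probes, gene: str, cn: int) -> "CnvSpec":
        """CN for every amplicon (PanelDesign) or target probe (ProbePanel)
        of ``gene``."""
        if isinstance(panel_or_probes, ProbePanel):
            ids = [p.id for p in panel_or_probes.targets(gene)]
        else:
            ids = [a.id for a in panel_or_probes.amplicons_for_gene(gene)]
        if not ids:
            raise ValueError(f"no targets for gene {gene!r}")
        return cls({i: cn for i in ids})

    @classmethod
    def exons(cls, ids: list[str], cn: int) -> "CnvSpec":
        return cls({i: cn for i in ids})


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative noise parameters (lognormal sigmas, natural log)."""

    efficiency_spread: float = 0.0   # per-amplicon, drawn once per cohort
    sample_noise_sd: float = 0.0     # per observation

    def __post_init__(self) -> None:
        if self.efficiency_spread < 0 or self.sample_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")


NOISELESS = NoiseModel()


def _efficiencies(
    ids: list[str], spread: float, rng: np.random.Generator
) -> dict[str, float]:
    if spread == 0:
        return {i: 1.0 for i in ids}
    return {i: float(v) for i, v in zip(ids, rng.lognormal(0.0, spread, len(ids)))}


def _obs_factor(noise: NoiseModel, rng: np.random.Generator, n: int) -> np.ndarray:
    if noise.sample_noise_sd == 0:
        return np.ones(n)
    return rng.lognormal(0.0, noise.sample_noise_sd, n)


# ---------------------------------------------------------------------------
# read counts


def gen_counts(
    panel: PanelDesign,
    cnv: CnvSpec = CnvSpec(),
    depth: int = 1000,
    noise: NoiseModel = NOISELESS,
    n_samples: int = 8,
    seed: int = 0,
    calibrate_gene_ratio: float | None = None,
    sample_prefix: str = "S",
) -> ReadCountMatrix:
    """Simulate a run's read-count matrix.

    ``depth`` is the expected diploid per-amplicon count.  Per-amplicon
    diploid expectations are quantized to even integers so noiseless CN=1
    counts are *exactly* half their diploid value.  Efficiencies are
    drawn once for the cohort; ``cnv`` applies to every sample (generate
    an affected sample against a normal cohort with
    :func:`gen_cohort_with_case`, which shares efficiencies through the
    seed).  ``calibrate_gene_ratio`` rescales gene-1 efficiencies per
    plex so the diploid per-plex (hence global) gene ratio equals the
    requested value.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    ids = [a.id for a in panel.amplicons]
    eff = _efficiencies(ids, noise.efficiency_spread, rng)
    if calibrate_gene_ratio is not None:
        g1, g2 = panel.gene_labels
        for plex in panel.plexes:
            ids1 = [a.id for a in panel.amplicons_for_gene(g1, plex_id=plex)]
            ids2 = [a.id for a in panel.amplicons_for_gene(g2, plex_id=plex)]
            s1 = sum(eff[i] for i in ids1)
            s2 = sum(eff[i] for i in ids2)
            f = calibrate_gene_ratio * s2 / s1
            for i in ids1:
                eff[i] *= f
    # even-integer diploid expectation per amplicon
    base = {i: max(2, 2 * int(round(depth * eff[i] / 2))) for i in ids}
    rows = {}
    for s in range(n_samples):
        factors = _obs_factor(noise, rng, len(ids))
        rows[f"{sample_prefix}{s + 1}"] = [
            int(round(base[i] * cnv.cn(i) / 2 * f))
            for i, f in zip(ids, factors)
        ]
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=ids)
    matrix = ReadCountMatrix(counts=counts, panel=panel)
    matrix.seed = seed  # type: ignore[attr-defined]
    return matrix


def gen_cohort_with_case(
    panel: PanelDesign,
    case_cnv: CnvSpec,
    n_normal: int = 8,
    depth: int = 1000,
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
    calibrate_gene_ratio: float | None = None,
    case_id: str = "CASE",
) -> ReadCountMatrix:
    """A diploid cohort plus one CNV-carrying sample, sharing efficiencies."""
    normal = gen_counts(
        panel, CnvSpec.diploid(), depth, noise, n_normal, seed,
        calibrate_gene_ratio,
    )
    case = gen_counts(
        panel, case_cnv, depth, noise, 1, seed, calibrate_gene_ratio,
        sample_prefix="_tmp",
    )
    case_row = case.counts.rename(index={"_tmp1": case_id})
    matrix = ReadCountMatrix(
        counts=pd.concat([normal.counts, case_row]), panel=panel
    )
    matrix.seed = seed  # type: ignore[attr-defined]
    return matrix


# ---------------------------------------------------------------------------
# fragment-analysis traces


@dataclass(frozen=True)
class TraceTruth:
    """Ground truth attached to a simulated trace (for oracle tests)."""

    slope: float        # bp per scan of the true affine model
    intercept: float    # bp at scan 0
    heights: dict[str, float]  # planted height per amplicon (0 = dropout)
    seed: int

    def bp_to_scan(self, bp: float) -> float:
        return (bp - self.intercept) / self.slope


def gen_trace(
    panel: PanelDesign,
    plex_id: str,
    cnv: CnvSpec = CnvSpec(),
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
    base_height: float = 2000.0,
    peak_sigma_scans: float = 3.0,
    standard: SizeStandardDef = LIZ_600,
    ladder_height: float = 800.0,
    slope: float = 0.25,
    intercept: float = 10.0,
    sample_id: str = "SIM",
    efficiencies: dict[str, float] | None = None,
) -> tuple[RawTrace, TraceTruth]:
    """Simulate a two-channel electropherogram for one plex.

    Gaussian peak per amplicon at its expected size, mapped through a
    known affine scan model (integer-bp sizes land on exact integer
    scans, so the noiseless chain is exactly invertible); heights are
    ``base_height * efficiency * CN/2``.  The ladder channel carries the
    size-standard fragments.  CN 0 plants no peak.

    ``efficiencies`` overrides the per-amplicon efficiency draw --
    efficiency is a property of the amplicon chemistry, so traces meant
    to be compared (sample vs reference) must share it; see
    :func:`gen_fa_case`.
    """
    if plex_id not in panel.plexes:
        raise ValueError(f"plex {plex_id!r} not in panel")
    rng = np.random.default_rng(seed)
    amps = panel.amplicons_in_plex(plex_id)
    if efficiencies is None:
        eff = _efficiencies([a.id for a in amps], noise.efficiency_spread, rng)
    else:
        eff = {a.id: efficiencies[a.id] for a in amps}
    max_bp = max(standard.fragment_sizes_bp[-1],
                 max(a.expected_length_bp for a in amps))
    n_scans = int(round((max_bp - intercept) / slope)) + 100
    scans = np.arange(n_scans)

    def gaussian(center: float, height: float) -> np.ndarray:
        return height * np.exp(-0.5 * ((scans - center) / peak_sigma_scans) ** 2)

    sample = np.zeros(n_scans)
    heights: dict[str, float] = {}
    factors = _obs_factor(noise, rng, len(amps))
    for a, f in zip(amps, factors):
        cn = cnv.cn(a.id)
        h = base_height * eff[a.id] * cn / 2 * f
        heights[a.id] = h
        if cn == 0 or h <= 0:
            continue
        center = round((a.expected_length_bp - intercept) / slope)
        sample += gaussian(center, h)

    ladder = np.zeros(n_scans)
    for size in standard.fragment_sizes_bp:
        center = round((size - intercept) / slope)
        ladder += gaussian(center, ladder_height)

    trace = RawTrace(
        sample_id=sample_id, plex_id=plex_id,
        channels={"sample": sample, "ladder": ladder},
    )
    truth = TraceTruth(slope=slope, intercept=intercept, heights=heights, seed=seed)
    return trace, truth


def gen_reference_traces(
    panel: PanelDesign,
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
    **kwargs,
) -> dict[str, tuple[RawTrace, TraceTruth]]:
    """A diploid trace for every plex (e.g. as the TN-CNV reference)."""
    return {
        plex: gen_trace(
            panel, plex, CnvSpec.diploid(), noise,
            seed=seed + i, sample_id="TN", **kwargs,
        )
        for i, plex in enumerate(panel.plexes)
    }


def gen_fa_case(
    panel: PanelDesign,
    cnv: CnvSpec = CnvSpec(),
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
    **kwargs,
) -> dict[str, tuple[RawTrace, RawTrace, TraceTruth, TraceTruth]]:
    """Per plex, a (sample, reference) trace pair with *shared* per-amplicon
    efficiencies and independent observation noise.

    Returns ``{plex: (sample_trace, reference_trace, sample_truth,
    reference_truth)}``.  Sharing efficiencies between the pair models
    reality -- amplification efficiency is amplicon-specific and
    reproducible across wells, which is what makes normalization against
    a reference meaningful at all.
    """
    rng = np.random.default_rng(seed)
    eff = _efficiencies(
        [a.id for a in panel.amplicons], noise.efficiency_spread, rng
    )
    out = {}
    for i, plex in enumerate(panel.plexes):
        sample, struth = gen_trace(
            panel, plex, cnv, noise, seed=seed + 1000 + i,
            sample_id="CASE", efficiencies=eff, **kwargs,
        )
        refer, rtruth = gen_trace(
            panel, plex, CnvSpec.diploid(), noise, seed=seed + 2000 + i,
            sample_id="TN", efficiencies=eff, **kwargs,
        )
        out[plex] = (sample, refer, struth, rtruth)
    return out


# ---------------------------------------------------------------------------
# dosage runs


def gen_dosage_run(
    probes: ProbePanel,
    cnv: CnvSpec = CnvSpec(),
    n_controls: int = 4,
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
    base_height: float = 2000.0,
) -> DosageRun:
    """Simulate a MAQ/MLPA run: diploid controls plus one test sample.

    Test-sample target heights are ``base * efficiency * CN/2``; CN 0
    produces an absent peak.  Reference probes are always two-copy.
    """
    if n_controls < 3:
        raise ValueError("need >= 3 control samples")
    rng = np.random.default_rng(seed)
    ids = [p.id for p in probes.probes]
    eff = _efficiencies(ids, noise.efficiency_spread, rng)

    def sample_heights(spec: CnvSpec) -> dict[str, float]:
        factors = _obs_factor(noise, rng, len(ids))
        out = {}
        for pid, f in zip(ids, factors):
            is_target = probes.probes[ids.index(pid)].role == "TARGET"
            cn = spec.cn(pid) if is_target else 2
            h = base_height * eff[pid] * cn / 2 * f
            if h > 0:
                out[pid] = float(h)
        return out

    controls = {
        f"CTRL{i + 1}": sample_heights(CnvSpec.diploid())
        for i in range(n_controls)
    }
    test = sample_heights(cnv)
    return DosageRun(panel=probes, test=test, controls=controls, seed=seed)
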