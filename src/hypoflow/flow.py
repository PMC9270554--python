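"""Quadrant classification and per-sample summaries for cytotoxicity cytometry.

Events carry five channels: forward/side scatter (FSC, SSC) and three
fluorescence channels — FL1 (NAO, cardiolipin/mitochondrial mass; or 2-NBDG,
glucose uptake), FL2 (TMRE, mitochondrial membrane potential) and FL3
(propidium iodide, membrane damage).  Each cell is assigned to one of four
phenotype quadrants:

    Q1  dead (PI-positive; MMP is ignored — dead cells never retain MMP)
    Q2  live, reduced cardiolipin (NAO-high), high MMP
    Q3  live apoptotic, oxidized cardiolipin (NAO-low)
    Q4  live, reduced cardiolipin, collapsed MMP

The cytotoxic endpoint is the fraction affected Fa = Q1 + Q3 (dead plus
live-apoptotic), the quantity the dose-response stage fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

CHANNELS = ("FSC", "SSC", "FL1", "FL2", "FL3")
QUADRANTS = ("Q1", "Q2", "Q3", "Q4")
ENVIRONMENTS = ("normoxia", "hypoxia")


@dataclass
class EventTable:
    """Per-cell channel intensities for one stained sample.

    ``data`` has one row per event and columns FSC, SSC, FL1, FL2, FL3 with
    strictly positive, finite values (arbitrary fluorescence units,
    log-transformable).  Metadata identify the treatment condition.
    ``stain`` records which dye FL1 reports ("NAO" or "2-NBDG") so that
    mitochondrial-mass and glucose-uptake semantics cannot be mixed.
    """

    data: pd.DataFrame
    drug: str = "none"
    dose: float = 0.0
    dose_unit: str = "uM"
    environment: str = "normoxia"
    replicate: int = 1
    stain: str = "NAO"

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise ValueError(f"event table missing channels: {missing}")
        self.data = self.data.loc[:, list(CHANNELS)].reset_index(drop=True)
        if self.environment not in ENVIRONMENTS:
            raise ValueError(
                f"environment must be one of {ENVIRONMENTS}, got {self.environment!r}"
            )
        vals = self.data.to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals <= 0)
        if bad.any():
            row = int(np.argwhere(bad)[0, 0])
            raise ValueError(
                f"non-positive or non-finite channel value at event row {row}"
            )

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class GateSet:
    """Quadrant gate thresholds (arbitrary intensity units, compared on the
    raw scale; thresholds are positive so the comparison is equivalent on the
    log scale)."""

    nao_threshold: float
    tmre_threshold: float
    pi_threshold: float

    def __post_init__(self) -> None:
        for name in ("nao_threshold", "tmre_threshold", "pi_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class QuadrantSummary:
    """Quadrant fractions, per-quadrant per-channel MFI, and Fa = Q1 + Q3.

    MFI of an empty quadrant is NaN (undefined), never zero.
    """

    fractions: Mapping[str, float]
    mfi: Mapping[str, Mapping[str, float]]
    n_events: int
    fa: float
    meta: Mapping[str, object] = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flatten into one tidy record (drug, dose, environment, replicate,
        q1..q4, fa, n_events, per-quadrant MFIs)."""
        row = dict(self.meta)
        for q in QUADRANTS:
            row[q.lower()] = self.fractions[q]
        row["fa"] = self.fa
        row["n_events"] = self.n_events
        for q in QUADRANTS:
            for ch in CHANNELS:
                row[f"mfi_{q.lower()}_{ch.lower()}"] = self.mfi[q][ch]
        return row


def classify_events(events: EventTable, gates: GateSet) -> np.ndarray:
    """Assign every event to exactly one quadrant.

    Rules applied in order of precedence:

    1. FL3 (PI) above threshold -> Q1 dead, regardless of other channels
       (dead cells never have MMP, so TMRE is ignored);
    2. else FL1 (NAO) at or below threshold -> Q3 live apoptotic (oxCL);
    3. else FL2 (TMRE) above threshold -> Q2 live, high MMP;
    4. else -> Q4 live, collapsed MMP.
    """
    if len(events) == 0:
        raise ValueError("cannot classify an empty event table")
    fl1 = events.data["FL1"].to_numpy()
    fl2 = events.data["FL2"].to_numpy()
    fl3 = events.data["FL3"].to_numpy()
    labels = np.select(
        [
            fl3 > gates.pi_threshold,
            fl1 <= gates.nao_threshold,
            fl2 > gates.tmre_threshold,
        ],
        ["Q1", "Q3", "Q2"],
        default="Q4",
    )
    return labels


def summarize_sample(
    events: EventTable,
    labels: np.ndarray,
    mfi_mode: str = "arithmetic",
) -> QuadrantSummary:
    """Collapse labelled events into fractions, per-quadrant MFIs and Fa.

    MFI is the arithmetic mean on the linear intensity scale by default, the
    conventional cytometry "mean fluorescence intensity"; ``mfi_mode
    ="geometric"`` switches to the geometric mean.
    """
    if len(labels) != len(events):
        raise ValueError("labels are not aligned to events")
    if mfi_mode not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown mfi_mode {mfi_mode!r}")
    n = len(events)
    labels = np.asarray(labels)
    fractions = {q: float(np.sum(labels == q)) / n for q in QUADRANTS}
    mfi: dict[str, dict[str, float]] = {}
    for q in QUADRANTS:
        sub = events.data.loc[labels == q]
        if len(sub) == 0:
            mfi[q] = {ch: float("nan") for ch in CHANNELS}
        elif mfi_mode == "arithmetic":
            mfi[q] = {ch: float(sub[ch].mean()) for ch in CHANNELS}
        else:
            mfi[q] = {ch: float(np.exp(np.log(sub[ch]).mean())) for ch in CHANNELS}
    fa = fractions["Q1"] + fractions["Q3"]
    meta = {
        "drug": events.drug,
        "dose": events.dose,
        "dose_unit": events.dose_unit,
        "environment": events.environment,
        "replicate": events.replicate,
    }
    return QuadrantSummary(fractions=fractions, mfi=mfi, n_events=n, fa=fa, meta=meta)


def scatter_pregate(
    events: EventTable,
    fsc_range: tuple[float, float],
    ssc_range: tuple[float, float],
) -> EventTable:
    """Optional rectangular FSC/SSC pre-gate to exclude debris; off by
    default since scatter is used only descriptively in this assay."""
    d = events.data
    keep = (
        d["FSC"].between(*fsc_range) & d["SSC"].between(*ssc_range)
    ).to_numpy()
    return EventTable(
        data=d.loc[keep].reset_index(drop=True),
        drug=events.drug,
        dose=events.dose,
        dose_unit=events.dose_unit,
        environment=events.environment,
        replicate=events.replicate,
        stain=events.stain,
    )


def _valley_threshold(values: np.ndarray, channel: str) -> float:
    """Threshold at the minimum-density valley between the two largest modes
    of the log10-intensity distribution; midpoint-of-range fallback (with a
    warning) when the distribution is unimodal."""
    logv = np.log10(values)
    lo, hi = logv.min(), logv.max()
    if hi - lo < 1e-9:
        warnings.warn(
            f"{channel}: degenerate intensity range; using midpoint threshold"
        )
        return float(10 ** lo)
    grid = np.linspace(lo, hi, 512)
    dens = gaussian_kde(logv)(grid)
    peaks, props = find_peaks(dens, height=0)
    if len(peaks) < 2:
        warnings.warn(
            f"{channel}: unimodal log-intensity distribution; "
            "falling back to midpoint of log-range"
        )
        return float(10 ** ((lo + hi) / 2))
    # two largest modes, in grid order
    order = np.argsort(props["peak_heights"])[::-1][:2]
    i, j = sorted(peaks[order])
    valley = i + int(np.argmin(dens[i : j + 1]))
    return float(10 ** grid[valley])


def auto_gates(events_list: Sequence[EventTable]) -> GateSet:
    """Derive gate thresholds from pooled control samples.

    For each fluorescence channel the threshold sits at the density valley
    between the two largest modes of the pooled log-intensity histogram.
    The original assay gated manually; this automated surrogate is only
    reproducible relative to the supplied controls.
    """
    if not events_list:
        raise ValueError("need at least one control sample")
    pooled = pd.concat([ev.data for ev in events_list], ignore_index=True)
    if len(pooled) < 100:
        raise ValueError(
            f"need at least 100 pooled control events, got {len(pooled)}"
        )
    return GateSet(
        nao_threshold=_valley_threshold(pooled["FL1"].to_numpy(), "FL1"),
        tmre_threshold=_valley_threshold(pooled["FL2"].to_numpy(), "FL2"),
        pi_threshold=_valley_threshold(pooled["FL3"].to_numpy(), "FL3"),
    )


def glucose_uptake_summary(events: EventTable) -> float:
    """MFI of FL1 over all events for a 2-NBDG-stained sample (glucose
    uptake proxy).  Rejects NAO-stained samples so mitochondrial-mass and
    glucose-uptake readouts cannot be conflated."""
    if len(events) == 0:
        raise ValueError("empty event table")
    if events.stain != "2-NBDG":
        raise ValueError(
            f"glucose uptake requires a 2-NBDG-stained sample, got stain "
            f"{events.stain!r}"
        )
    return float(events.data["FL1"].mean())
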