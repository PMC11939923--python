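"""Per-participant evaluation: scan all ICs, pick the best, tally ROIs,
compare frequency bands, and assemble report tables.

For every band-filtered dataset each IC is scored by the full feature →
selection → MD-classification chain under repeated cross-validation.  ICs
above an accuracy threshold (0.70 for the right-vs-left investigation,
0.59 for extension-vs-flexion, falling back to 0.55 when empty) are
candidates; the best-performing IC is the highest-accuracy candidate whose
topography peaks within reach of a cortical ROI.  A stricter screen
(> 77% RLI, > 67.5% EFI) gates the ROI activity tallies: T1 counts ROIs
per participant, T2 counts participants per ROI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .discriminate import cross_validate
from .features import FeatureIndexMap, build_index_map, extract_features
from .ica import (DEFAULT_BANDS, ICADecomposition, bandpass_decompose,
                  ica_decompose, make_topography, match_roi)
from .montage import ROI_NAMES, Montage, roi_coordinates

__all__ = [
    "CANDIDATE_THRESHOLDS",
    "ROI_SCREEN_THRESHOLDS",
    "ICEvaluation",
    "ROITally",
    "BandWinnerTable",
    "EvaluationReport",
    "evaluate_all_ics",
    "select_best_ic",
    "tally_rois",
    "band_analysis",
    "summarise",
    "run_dataset",
]

#: Candidate-IC accuracy thresholds per investigation (with the EFI
#: fallback applied when no IC clears the primary threshold).
CANDIDATE_THRESHOLDS = {"RLI": (0.70,), "EFI": (0.59, 0.55)}

#: Stricter accuracy screens gating the ROI analysis.
ROI_SCREEN_THRESHOLDS = {"RLI": 0.77, "EFI": 0.675}

BAND_ORDER = tuple(b.name for b in DEFAULT_BANDS)


def _investigation_of(dataset: str) -> str:
    return "RLI" if dataset.lower() == "rli" else "EFI"


@dataclass
class ICEvaluation:
    """Per-IC accuracies of one band-filtered dataset and the chosen best."""

    dataset: str
    band: str
    accuracies: np.ndarray
    threshold_used: float
    candidates: np.ndarray            # IC indices at/above threshold
    best_ic: int | None
    best_accuracy: float              # nan when no best IC
    matched_rois: list
    best_topography: object | None = None   # Topography of the best IC

    @property
    def flagged_empty(self) -> bool:
        return self.best_ic is None


def evaluate_all_ics(decomp: ICADecomposition, index_map: FeatureIndexMap,
                     labels, *, t0_ms: float = -3000.0, folds: int = 100,
                     seed: int = 0, selection_mode: str = "per-fold",
                     k: int = 20) -> np.ndarray:
    """Mean CV accuracy of every IC: extract features → select → classify."""
    accs = np.empty(decomp.n_components)
    for ic in range(decomp.n_components):
        ft = extract_features(decomp.activations[:, ic, :], index_map,
                              decomp.fs, t0_ms=t0_ms, labels=labels)
        cv = cross_validate(ft, folds=folds, seed=seed + ic,
                            selection_mode=selection_mode, k=k)
        accs[ic] = cv.mean
    return accs


def select_best_ic(accuracies: np.ndarray, decomp: ICADecomposition,
                   montage: Montage, investigation: str, *,
                   dataset: str = "", band: str = "",
                   rois: pd.DataFrame | None = None,
                   radius_cm: float = 3.0) -> ICEvaluation:
    """Apply the candidate threshold (with EFI fallback) and pick the
    highest-accuracy candidate whose topography matches at least one ROI."""
    investigation = investigation.upper()
    if investigation not in CANDIDATE_THRESHOLDS:
        raise ValueError(f"investigation must be RLI or EFI, got "
                         f"{investigation!r}")
    if rois is None:
        rois = roi_coordinates()
    accuracies = np.asarray(accuracies, float)
    candidates = np.empty(0, int)
    threshold = CANDIDATE_THRESHOLDS[investigation][0]
    for thr in CANDIDATE_THRESHOLDS[investigation]:
        threshold = thr
        candidates = np.flatnonzero(accuracies >= thr)
        if len(candidates):
            break
    best_ic, best_acc, matched, best_topo = None, float("nan"), [], None
    for ic in candidates[np.argsort(-accuracies[candidates], kind="stable")]:
        topo = make_topography(decomp, int(ic), montage)
        hits = match_roi(topo, rois, radius_cm)
        if hits:
            best_ic, best_acc, matched = int(ic), float(accuracies[ic]), hits
            best_topo = topo
            break
    return ICEvaluation(dataset, band, accuracies, threshold, candidates,
                        best_ic, best_acc, matched, best_topo)


# ---------------------------------------------------------------------------
# ROI tallies and band analysis

@dataclass
class ROITally:
    """Indicator matrix of supra-threshold ROI activity with T1/T2 sums."""

    indicator: pd.DataFrame    # participants x 7 ROIs, bool

    @property
    def t1(self) -> pd.Series:
        """ROIs showing discriminatory activity, per participant."""
        return self.indicator.sum(axis=1)

    @property
    def t2(self) -> pd.Series:
        """Occurrences of each ROI's activity across participants."""
        return self.indicator.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.indicator.to_numpy().sum())

    def to_frame(self) -> pd.DataFrame:
        df = self.indicator.astype(int).copy()
        df["T1"] = self.t1
        t2 = self.t2.astype(int)
        t2["T1"] = self.grand_total
        df.loc["T2"] = t2
        return df


def tally_rois(evaluations: dict, investigation: str) -> ROITally:
    """Union of matched ROIs over a participant's supra-threshold best ICs.

    *evaluations* maps participant id → iterable of :class:`ICEvaluation`
    (one per band).  Only best ICs whose accuracy exceeds the ROI screen
    (77% RLI / 67.5% EFI) contribute.
    """
    screen = ROI_SCREEN_THRESHOLDS[investigation.upper()]
    rows = {}
    for participant, evals in evaluations.items():
        active = set()
        for ev in evals:
            if ev.best_ic is not None and ev.best_accuracy > screen:
                active.update(ev.matched_rois)
        rows[participant] = {roi: roi in active for roi in ROI_NAMES}
    indicator = pd.DataFrame.from_dict(rows, orient="index",
                                       columns=list(ROI_NAMES)).fillna(False)
    return ROITally(indicator)


@dataclass
class BandWinnerTable:
    """Which band carries each participant's best accuracy."""

    winners: pd.DataFrame      # participant, winning band(s), headline band
    counts: pd.Series          # per-band headline counts

    @property
    def n_participants(self) -> int:
        return len(self.winners)


def band_analysis(acc_table: pd.DataFrame,
                  band_order=BAND_ORDER) -> BandWinnerTable:
    """Per-participant argmax across band columns.

    Ties are all reported; the headline count goes to the first tied band
    in canonical band order.  Rows that are entirely missing are skipped.
    """
    bands = [b for b in band_order if b in acc_table.columns]
    if not bands:
        raise ValueError("accuracy table has no recognised band columns")
    rows = []
    for participant, row in acc_table[bands].iterrows():
        vals = row.astype(float)
        if vals.isna().all():
            continue
        best = vals.max()
        tied = [b for b in bands if np.isclose(vals[b], best, atol=1e-9)]
        rows.append((participant, best, tied, tied[0]))
    winners = pd.DataFrame(rows, columns=["participant", "best_accuracy",
                                          "tied_bands", "headline_band"])
    counts = winners["headline_band"].value_counts().reindex(
        bands, fill_value=0)
    return BandWinnerTable(winners, counts)


# ---------------------------------------------------------------------------
# report assembly

@dataclass
class EvaluationReport:
    """Aggregated per-participant tables: accuracies, ROI tallies, winners."""

    accuracy_table: pd.DataFrame          # participants x bands (fractions)
    roi_tally: ROITally | None = None
    band_winners: BandWinnerTable | None = None
    metadata: dict = field(default_factory=dict)

    def accuracy_summary(self) -> pd.DataFrame:
        """Percent table with a 'max-of-bands' column and mean/SD rows;
        missing cells render as 'N/A' on export."""
        df = self.accuracy_table.astype(float) * 100.0
        df["max_of_bands"] = df.max(axis=1)
        means = df.mean(axis=0, skipna=True)
        sds = df.std(axis=0, ddof=1)
        df.loc["mean"] = means
        df.loc["sd"] = sds
        return df

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.accuracy_summary().to_csv(out / "accuracies.tsv", sep="\t",
                                       na_rep="N/A")
        if self.roi_tally is not None:
            self.roi_tally.to_frame().to_csv(out / "roi_tally.tsv", sep="\t")
        if self.band_winners is not None:
            self.band_winners.winners.to_csv(out / "band_winners.tsv",
                                             sep="\t", index=False)
        payload = dict(self.metadata)
        payload["mean_accuracies"] = {
            c: (None if np.isnan(v) else float(v))
            for c, v in (self.accuracy_table.mean(axis=0) * 100).items()
        }
        if self.band_winners is not None:
            payload["band_winner_counts"] = {
                k: int(v) for k, v in self.band_winners.counts.items()}
        if self.roi_tally is not None:
            payload["roi_t2"] = {k: int(v)
                                 for k, v in self.roi_tally.t2.items()}
            payload["roi_grand_total"] = self.roi_tally.grand_total
        (out / "report.json").write_text(json.dumps(payload, indent=1))
        return out


def summarise(per_participant: dict, investigation: str,
              metadata: dict | None = None) -> EvaluationReport:
    """Build the report from ``{participant: {band: ICEvaluation | None}}``.

    Participants with missing bands get NaN cells (exported as 'N/A').
    """
    table = {}
    evals_by_participant = {}
    for participant, by_band in per_participant.items():
        row = {}
        evs = []
        for band in BAND_ORDER:
            ev = by_band.get(band)
            if ev is None or ev.best_ic is None:
                row[band] = np.nan
            else:
                row[band] = ev.best_accuracy
                evs.append(ev)
        table[participant] = row
        evals_by_participant[participant] = evs
    acc_table = pd.DataFrame.from_dict(table, orient="index",
                                       columns=list(BAND_ORDER))
    tally = tally_rois(evals_by_participant, investigation)
    winners = (band_analysis(acc_table)
               if not acc_table.isna().all(axis=None) else None)
    return EvaluationReport(acc_table, tally, winners,
                            dict(metadata or {},
                                 investigation=investigation.upper()))


# ---------------------------------------------------------------------------
# single-dataset convenience runner

def run_dataset(ts, dataset: str, band, *, seed: int = 0,
                folds: int = 100, selection_mode: str = "per-fold",
                k: int = 20, max_fit_samples: int | None = 50_000,
                radius_cm: float = 3.0) -> ICEvaluation:
    """Band-filter one analysis dataset, decompose, scan ICs, pick the best.

    *ts* is an artifact-free :class:`TrialSet` with binary labels; *band*
    is a :class:`BandDefinition`.
    """
    from .ica import bandpass_filter

    filtered = bandpass_filter(ts, band)
    decomp = ica_decompose(filtered, seed=seed,
                           max_fit_samples=max_fit_samples)
    index_map = build_index_map(band)
    accs = evaluate_all_ics(decomp, index_map, ts.labels,
                            t0_ms=ts.t_start_ms, folds=folds, seed=seed,
                            selection_mode=selection_mode, k=k)
    return select_best_ic(accs, decomp, ts.montage,
                          _investigation_of(dataset), dataset=dataset,
                          band=band.name, radius_cm=radius_cm)
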