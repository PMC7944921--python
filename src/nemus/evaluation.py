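"""Scoring of inference runs against simulation truth.

Summaries mirror the quantities the simulation study reports: outcome
proportions per treatment block, Pearson correlations between true and
estimated fitness profiles (over the 19 free entries) and between true and
estimated root codon frequencies (over a 60-entry free subset), the
time-depth of the true shift joined to the outcome, and the fold change in
fitness RMSE when root frequencies are ignored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mutsel_core import FitnessProfile
from .shift_search import SearchResult, classify_outcome

__all__ = [
    "OUTCOME_LABELS",
    "fitness_correlation",
    "root_frequency_correlation",
    "error_fold_change",
    "BlockSummary",
    "summarise_block",
    "summarise_archives",
]

OUTCOME_LABELS = (
    "correct_only",
    "correct_plus_false",
    "incorrect_only",
    "optimisation_failure",
    "none_returned",
)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def fitness_correlation(true: FitnessProfile, est: FitnessProfile) -> float:
    """Pearson r between the 19 free relative fitnesses (anchor excluded);
    NaN when either vector has zero variance."""
    return _pearson(true.free, est.free)


def root_frequency_correlation(true, est) -> float:
    """Pearson r between root codon frequency vectors over the 60 free
    coordinates (the last, constrained, coordinate is dropped)."""
    true = np.asarray(true, dtype=float)
    est = np.asarray(est, dtype=float)
    if true.shape != (61,) or est.shape != (61,):
        raise ValueError("root frequency vectors must have length 61")
    return _pearson(true[:60], est[:60])


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


def error_fold_change(true_f, est_with_root, est_without_root) -> float:
    """RMSE(estimates ignoring root frequencies) / RMSE(estimates modelling
    them), both against the true 19 free fitnesses.  > 1 means ignoring
    non-equilibrium initial frequencies inflated the error."""
    true_f = np.asarray(true_f, dtype=float)
    if true_f.shape != (19,):
        raise ValueError("expected 19 free fitnesses")
    denom = _rmse(est_with_root, true_f)
    numer = _rmse(est_without_root, true_f)
    if denom == 0:
        import warnings

        warnings.warn("zero RMSE in root-aware estimates; fold change is infinite")
        return math.inf
    return numer / denom


@dataclass
class BlockSummary:
    table: pd.DataFrame
    proportions: dict[str, float]
    n_missing: int

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False)


def summarise_block(records: list[dict]) -> BlockSummary:
    """Summarise one treatment block.

    Each record carries ``truth`` (a dict with ``shift_branch``,
    ``shift_time_depth``, ``base_profile``, optional ``shift_profile`` and
    ``root_frequencies``) and ``result`` (a :class:`SearchResult`, or a dict
    with the same fields, or None for a missing replicate).
    """
    rows = []
    n_missing = 0
    for i, rec in enumerate(records):
        truth = rec["truth"]
        result = rec.get("result")
        if result is None:
            n_missing += 1
            rows.append({"replicate": i, "outcome": "missing"})
            continue
        if isinstance(result, SearchResult):
            inferred = result.shift_branches
            profiles = [list(p.f) for p in result.profiles]
            root_est = result.root_frequencies
            res_outcome = result.outcome
        else:
            inferred = result["shift_branches"]
            profiles = result["profiles"]
            root_est = result.get("root_frequencies")
            res_outcome = result.get("outcome", "shifts_found")
        true_branch = truth.get("shift_branch")
        true_set = set() if true_branch is None else {true_branch}
        stub = _StubResult(inferred, res_outcome)
        outcome = classify_outcome(stub, true_set)
        row = {
            "replicate": i,
            "outcome": outcome,
            "n_inferred": len(inferred),
            "shift_time_depth": truth.get("shift_time_depth"),
        }
        base_true = FitnessProfile(tuple(truth["base_profile"]))
        base_est = FitnessProfile(tuple(profiles[0]))
        row["r_root_model"] = fitness_correlation(base_true, base_est)
        if true_branch is not None and true_branch in inferred:
            k = inferred.index(true_branch) + 1
            shift_est = FitnessProfile(tuple(profiles[k]))
            shift_true = FitnessProfile(tuple(truth["shift_profile"]))
            row["r_shift_model"] = fitness_correlation(shift_true, shift_est)
        if truth.get("root_frequencies") is not None and root_est is not None:
            row["r_root_frequencies"] = root_frequency_correlation(
                truth["root_frequencies"], root_est
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    scored = table[table["outcome"] != "missing"]
    if len(scored):
        props = {
            lab: float((scored["outcome"] == lab).mean()) for lab in OUTCOME_LABELS
        }
        extra = {"true_negative", "false_positive"} & set(scored["outcome"])
        for lab in sorted(extra):
            props[lab] = float((scored["outcome"] == lab).mean())
    else:
        props = {lab: math.nan for lab in OUTCOME_LABELS}
    return BlockSummary(table=table, proportions=props, n_missing=n_missing)


class _StubResult:
    """Minimal duck-typed stand-in accepted by classify_outcome."""

    def __init__(self, shift_branches, outcome):
        self.shift_branches = list(shift_branches)
        self.outcome = outcome


def summarise_archives(archive_dir: str | Path, results_dir: str | Path) -> BlockSummary:
    """File-based wrapper: read ``rep_*.truth.json`` from the archive and
    matching ``rep_*.result.json`` from the results directory."""
    archive_dir = Path(archive_dir)
    results_dir = Path(results_dir)
    records = []
    for truth_path in sorted(archive_dir.glob("rep_*.truth.json")):
        truth_raw = json.loads(truth_path.read_text())
        cfg = truth_raw["configuration"]
        truth = {
            "shift_branch": truth_raw.get("shift_branch"),
            "shift_time_depth": truth_raw.get("shift_time_depth"),
            "base_profile": cfg["base_profile"],
            "root_frequencies": (
                None
                if cfg["root_frequencies"] == "equilibrium"
                else cfg["root_frequencies"]
            ),
        }
        if cfg["shifts"]:
            truth["shift_profile"] = cfg["shifts"][0]["profile"]
        stem = truth_path.name.replace(".truth.json", "")
        result_path = results_dir / f"{stem}.result.json"
        result = (
            json.loads(result_path.read_text()) if result_path.exists() else None
        )
        records.append({"truth": truth, "result": result})
    return summarise_block(records)
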