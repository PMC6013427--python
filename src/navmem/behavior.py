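"""Behavioral scoring: percentile-rank accuracy, memory labels, spatial bins,
and the in-task points economy.

The accuracy score normalizes the raw Euclidean response error by ranking it
against all possible errors given the target's position, so scores are
comparable across targets near boundaries and near the center: 1 is a perfect
response and 0 the unique worst possible one.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ArenaConfig, TaskSession

__all__ = [
    "accuracy_score",
    "label_memory",
    "spatial_bin",
    "score_points",
    "score_session",
    "behavioral_summary",
]

_TOL = 1e-9

POINTS_TABLE = {
    ("Yes", True): 200,
    ("Yes", False): -350,
    ("Maybe", True): 100,
    ("Maybe", False): -50,
    ("No", True): 50,
    ("No", False): 0,
}


def _candidate_grid(arena: ArenaConfig, grid_step: float) -> tuple[np.ndarray, np.ndarray]:
    nx = int(np.floor(arena.width / grid_step + _TOL)) + 1
    ny = int(np.floor(arena.height / grid_step + _TOL)) + 1
    gx = np.arange(nx) * grid_step
    gy = np.arange(ny) * grid_step
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    return xx.ravel(), yy.ravel()


def accuracy_score(
    true_location,
    response_location,
    arena: ArenaConfig | None = None,
    grid_step: float = 1.0,
) -> float:
    """Percentile rank of the response error among all possible errors.

    Candidate response locations are enumerated on a uniform grid with
    spacing ``grid_step`` covering the arena.  Candidates whose error to the
    true location strictly exceeds the observed error count fully; exact ties
    count half, excluding the observed candidate itself from both the tie
    count and the denominator.  A zero-error response scores exactly 1 and
    the unique maximal-error response exactly 0.
    """
    arena = arena or ArenaConfig()
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    tx, ty = map(float, true_location)
    rx, ry = map(float, response_location)
    for x, y in ((tx, ty), (rx, ry)):
        if not arena.contains(x, y):
            raise ValueError(f"location ({x}, {y}) outside arena")
    cx, cy = _candidate_grid(arena, grid_step)
    if cx.size < 2:
        raise ValueError("grid must contain at least 2 candidate locations")
    cand_err = np.hypot(cx - tx, cy - ty)
    observed = float(np.hypot(rx - tx, ry - ty))
    greater = int(np.count_nonzero(cand_err > observed + _TOL))
    equal = int(np.count_nonzero(np.abs(cand_err - observed) <= _TOL))
    # if the response coincides with a grid candidate, exclude that candidate
    on_grid = np.any((np.abs(cx - rx) <= _TOL) & (np.abs(cy - ry) <= _TOL))
    if on_grid:
        equal -= 1
    return (greater + 0.5 * equal) / (cand_err.size - 1)


def label_memory(responses: pd.DataFrame) -> pd.DataFrame:
    """Median-split subsequent-memory labels.

    A response is ``remembered`` iff its accuracy strictly exceeds the
    subject's median accuracy across all responses (all sessions pooled) and
    confidence was Yes or Maybe.  Returns a copy of ``responses`` with
    ``label`` in {remembered, forgotten} and ``subject_median_accuracy``.
    """
    if len(responses) < 2:
        raise ValueError("need at least 2 responses to form a median split")
    if responses["confidence"].isna().any():
        raise ValueError("missing confidence")
    bad = set(responses["confidence"]) - {"Yes", "Maybe", "No"}
    if bad:
        raise ValueError(f"unknown confidence values: {bad}")
    if "accuracy" not in responses or responses["accuracy"].isna().any():
        raise ValueError("all responses need an accuracy score")
    out = responses.copy()
    median = float(out["accuracy"].median())
    remembered = (out["accuracy"] > median) & out["confidence"].isin(["Yes", "Maybe"])
    out["label"] = np.where(remembered, "remembered", "forgotten")
    out["subject_median_accuracy"] = median
    return out


def spatial_bin(location, arena: ArenaConfig, test_viewpoint) -> dict:
    """Assign a location to the inner/boundary region and near/far half.

    The inner region is a centered rectangle with the arena's aspect ratio
    and exactly half the total area (sides scaled by 1/sqrt(2)); near/far
    halves split the arena at the midline perpendicular to the long
    (viewpoint) axis, near being the half containing ``test_viewpoint``.
    """
    x, y = map(float, location)
    if not arena.contains(x, y):
        raise ValueError(f"location ({x}, {y}) outside arena")
    s = 1.0 / np.sqrt(2.0)
    half_w = arena.width * s / 2.0
    half_h = arena.height * s / 2.0
    cx, cy = arena.width / 2.0, arena.height / 2.0
    inner = abs(x - cx) <= half_w and abs(y - cy) <= half_h
    vx = float(test_viewpoint[0])
    near = (x <= cx) == (vx <= cx)
    return {"region": "inner" if inner else "boundary", "half": "near" if near else "far"}


def score_points(confidence: str, correct: bool) -> int:
    """Signed points for one retrieval, per the confidence-weighted payoff."""
    try:
        return POINTS_TABLE[(confidence, bool(correct))]
    except KeyError:
        raise ValueError(f"unknown confidence {confidence!r}") from None


def score_session(session: TaskSession, grid_step: float = 1.0) -> pd.DataFrame:
    """Score every retrieval response of a session.

    Adds raw_error, accuracy (percentile rank), points (circle-containment
    rule at the arena's response-circle radius), spatial bins, and the
    median-split memory label.
    """
    arena = session.arena
    resp = session.responses.copy()
    err = np.hypot(
        resp["response_x"] - resp["true_x"], resp["response_y"] - resp["true_y"]
    )
    resp["raw_error"] = err
    resp["accuracy"] = [
        accuracy_score((r.true_x, r.true_y), (r.response_x, r.response_y), arena, grid_step)
        for r in resp.itertuples()
    ]
    resp["correct"] = err <= arena.response_circle_radius
    resp["points"] = [
        score_points(c, k) for c, k in zip(resp["confidence"], resp["correct"])
    ]
    bins = [
        spatial_bin((r.true_x, r.true_y), arena, (r.viewpoint_x, r.viewpoint_y))
        for r in resp.itertuples()
    ]
    resp["region"] = [b["region"] for b in bins]
    resp["half"] = [b["half"] for b in bins]
    return label_memory(resp)


def behavioral_summary(scored: pd.DataFrame) -> dict:
    """Per-subject behavioral summary (JSON-serializable)."""
    return {
        "n_responses": int(len(scored)),
        "mean_accuracy": float(scored["accuracy"].mean()),
        "median_accuracy": float(scored["subject_median_accuracy"].iloc[0]),
        "accuracy_by_confidence": {
            c: float(g["accuracy"].mean())
            for c, g in scored.groupby("confidence", observed=True)
        },
        "accuracy_by_region": {
            c: float(g["accuracy"].mean()) for c, g in scored.groupby("region")
        },
        "accuracy_by_half": {
            c: float(g["accuracy"].mean()) for c, g in scored.groupby("half")
        },
        "total_points": int(scored["points"].sum()),
        "n_remembered": int((scored["label"] == "remembered").sum()),
        "n_forgotten": int((scored["label"] == "forgotten").sum()),
    }


def write_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2))
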