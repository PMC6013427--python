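"""Shared fixtures: small synthetic sessions/recordings and the (expensive,
session-scoped) planted-effect recovery cohort reused by several tests."""

from __future__ import annotations

import warnings

import pandas as pd
import pytest

from navmem import preprocess as pre
from navmem import spectral as spec
from navmem.pipeline import (
    RunConfig,
    cohort_stats,
    effects_on_neural,
    run_subjects,
)
from navmem.synthetic import (
    NeuralModel,
    default_montage,
    generate_recording,
    generate_session,
    scaled_task,
)

warnings.filterwarnings("ignore", message=".*empty condition.*")
warnings.filterwarnings("ignore", message=".*single-class training.*")

SMALL_GRID = spec.FrequencyGrid(n=12, lo=1.0, hi=40.0)


@pytest.fixture(scope="session")
def small_session():
    return generate_session(task=scaled_task(6), seed=11)


@pytest.fixture(scope="session")
def small_recording(small_session):
    return generate_recording(
        small_session, default_montage(), NeuralModel(), fs=500.0, seed=12
    )


@pytest.fixture(scope="session")
def bipolar_notched(small_recording):
    return pre.notch_filter(pre.bipolar_reference(small_recording))


def recovery_config(seed: int, n_subjects: int = 20) -> RunConfig:
    """The planted-effect study condition at test scale: 20 subjects,
    10-trial sessions, left-memory and right-navigation gains of 2."""
    return RunConfig(
        n_subjects=n_subjects,
        seed=seed,
        task=scaled_task(10),
        neural=effects_on_neural(),
        grid=SMALL_GRID,
        bands=("low_theta",),
    )


@pytest.fixture(scope="session")
def recovery_runs():
    """Full-pipeline recovery over 10 seeds (shared across tests)."""
    runs = []
    for seed in range(10):
        cfg = recovery_config(seed)
        results = run_subjects(cfg)
        report = cohort_stats(results, cfg)
        runs.append(
            {
                "report": report,
                "narrowband": pd.concat(
                    [r.narrowband for r in results], ignore_index=True
                ),
            }
        )
    return runs


def decoding_features(cfg: RunConfig, i: int, freq_set: str = "low"):
    """Decoding features for one subject without the main-grid power pass."""
    from navmem import behavior as beh
    from navmem import classify as clf

    ss = cfg.subject_seed(i)
    s_sess, s_rec, _ = ss.spawn(3)
    session = generate_session(cfg.task, cfg.arena, cfg.behavior, s_sess, f"S{i:02d}")
    scored = beh.score_session(session, cfg.accuracy_grid_step)
    labels = dict(zip(scored["object_id"], scored["label"]))
    rec = generate_recording(session, default_montage(), cfg.neural, cfg.fs, s_rec)
    bip = pre.notch_filter(pre.bipolar_reference(rec), cfg.notch_band)
    ev = session.events
    sets = {
        tag: pre.extract_epochs(
            bip,
            ev[ev["event"] == tag],
            cfg.item_window_ms if tag in ("encoding", "no_item") else None,
            cfg.buffer_ms,
        )
        for tag in ("encoding", "no_item", "navigation", "baseline")
    }
    for es in sets.values():
        pre.kurtosis_reject(es, cfg.kurtosis_threshold)
    grid = spec.ExplicitGrid(tuple(clf.classifier_frequencies(freq_set)), cfg.grid.wavenumber)
    z = spec.log_and_zscore(spec.event_power(sets, grid))
    enc = (z.events["event"] == "encoding").to_numpy()
    enc_events = z.events[enc].reset_index(drop=True)
    return clf.build_features(
        z.values[enc],
        enc_events,
        enc_events["object_id"].map(labels).to_numpy(),
        z.freqs,
        z.channels,
        fold_by="trial",
    )


@pytest.fixture(scope="session")
def null_cohort_features():
    """Features of a small all-gains-off cohort for chance-level decoding.

    Full-length sessions: pooled AUC under leave-one-trial-out carries a
    pessimistic small-fold bias that only realistic event counts tame.
    """
    cfg = RunConfig(n_subjects=4, seed=202, neural=NeuralModel(), grid=SMALL_GRID)
    return [decoding_features(cfg, i) for i in range(cfg.n_subjects)]


@pytest.fixture(scope="session")
def effects_cohort_features():
    """Features of a small effects-on cohort (low and high sets)."""
    cfg = RunConfig(
        n_subjects=5,
        seed=303,
        task=scaled_task(8),
        neural=effects_on_neural(),
        grid=SMALL_GRID,
        bands=("low_theta",),
        decode=True,
        decode_freq_sets=("low", "high"),
    )
    return run_subjects(cfg)
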