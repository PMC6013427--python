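"""End-to-end orchestration: cohort simulation through the analysis battery.

``run_subjects`` takes each synthetic subject from session generation to
z-scored band power and subject-level effect rows; ``cohort_stats`` runs the
group battery (band x hemisphere x contrast t tests with Bonferroni across
the six hippocampal band tests, the hemisphere x condition lateralization
ANOVA and its variant forms, a narrowband-oscillation summary, and optional
decoding); ``run_pipeline`` chains the two and writes the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import classify as clf
from . import preprocess as pre
from . import spectral as spec
from . import stats as st
from .synthetic import (
    ArenaConfig,
    BehaviorModel,
    NeuralModel,
    TaskConfig,
    default_montage,
    generate_recording,
    generate_session,
)

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "SubjectResult",
    "subject_effect_rows",
    "run_subject",
    "run_subjects",
    "cohort_stats",
    "run_pipeline",
    "subset_filter",
    "effects_on_neural",
]

CONTRAST_CONDITIONS = {
    "memory": ("remembered", "forgotten"),
    "navigation": ("navigation", "baseline"),
    "item": ("encoding", "no_item"),
}


def effects_on_neural(**overrides) -> NeuralModel:
    """The planted-effect condition: left memory and right navigation gains."""
    params = dict(left_memory_gain=2.0, right_nav_gain=2.0, hfa_item_gain=1.5)
    params.update(overrides)
    return NeuralModel(**params)


@dataclass
class RunConfig:
    """Every tunable of the pipeline with its default, plus the master seed."""

    n_subjects: int = 12
    seed: int = 0
    task: TaskConfig = field(default_factory=TaskConfig)
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    behavior: BehaviorModel = field(default_factory=BehaviorModel)
    neural: NeuralModel = field(default_factory=NeuralModel)
    fs: float = 500.0
    contacts_per_probe: int = 5
    grid: spec.FrequencyGrid = field(default_factory=spec.FrequencyGrid)
    bands: tuple = ("low_theta", "theta", "hfa")
    accuracy_grid_step: float = 1.0
    buffer_ms: float = 3000.0
    notch_band: tuple = (58.0, 62.0)
    kurtosis_threshold: float = 5.0
    item_window_ms: tuple = (0.0, 1500.0)
    cluster_n_perm: int = 1000
    signflip_n_perm: int = 1000
    penalty_c: float = 1.0
    decode: bool = False
    decode_freq_sets: tuple = ("low", "high")
    n_shuffles: int = 0
    region: str = "hippocampus"

    def subject_seed(self, i: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(entropy=self.seed, spawn_key=(i,))


@dataclass
class SubjectResult:
    subject: str
    channels: pd.DataFrame  # bipolar montage
    behavioral: dict
    rejection: pd.DataFrame
    effects: pd.DataFrame  # subject x hemisphere x band x contrast rows
    condition_means: pd.DataFrame
    narrowband: pd.DataFrame
    features: dict  # freq_set -> FeatureMatrix
    neural: NeuralModel


def _condition_masks(events: pd.DataFrame, labels: dict) -> dict[str, np.ndarray]:
    """Event masks for every condition used by the contrasts."""
    ev = events["event"].to_numpy()
    masks = {tag: ev == tag for tag in ("encoding", "no_item", "navigation", "baseline")}
    label_of = events["object_id"].map(labels)
    masks["remembered"] = (ev == "encoding") & (label_of == "remembered").to_numpy()
    masks["forgotten"] = (ev == "encoding") & (label_of == "forgotten").to_numpy()
    return masks


def run_subject(config: RunConfig, i: int) -> SubjectResult:
    """Simulate and analyze one subject: session -> effects table rows."""
    ss = config.subject_seed(i)
    s_session, s_rec, s_decode = ss.spawn(3)
    subject = f"S{i:02d}"
    session = generate_session(
        config.task, config.arena, config.behavior, seed=s_session, subject=subject
    )
    scored = beh.score_session(session, config.accuracy_grid_step)
    labels = dict(zip(scored["object_id"], scored["label"]))

    montage = default_montage(contacts_per_probe=config.contacts_per_probe)
    recording = generate_recording(session, montage, config.neural, config.fs, seed=s_rec)
    bip = pre.bipolar_reference(recording)
    bip = pre.notch_filter(bip, stop_band=config.notch_band)

    ev = session.events
    sets = {
        "encoding": pre.extract_epochs(
            bip, ev[ev["event"] == "encoding"], config.item_window_ms, config.buffer_ms
        ),
        "no_item": pre.extract_epochs(
            bip, ev[ev["event"] == "no_item"], config.item_window_ms, config.buffer_ms
        ),
        "navigation": pre.extract_epochs(
            bip, ev[ev["event"] == "navigation"], None, config.buffer_ms
        ),
        "baseline": pre.extract_epochs(
            bip, ev[ev["event"] == "baseline"], None, config.buffer_ms
        ),
    }
    for es in sets.values():
        pre.kurtosis_reject(es, config.kurtosis_threshold)
    rejection = pre.rejection_report(list(sets.values()), bip.montage)

    power = spec.event_power(sets, config.grid)
    z = spec.log_and_zscore(power)
    masks = _condition_masks(z.events, labels)
    effects, cond_means = subject_effect_rows(z, labels, subject, config)

    narrowband = _narrowband_rows(power, masks, subject, config)

    features = {}
    if config.decode:
        features = _subject_features(sets, labels, config)

    return SubjectResult(
        subject=subject,
        channels=bip.montage,
        behavioral=beh.behavioral_summary(scored),
        rejection=rejection,
        effects=effects,
        condition_means=cond_means,
        narrowband=narrowband,
        features=features,
        neural=config.neural,
    )


def subject_effect_rows(
    z: spec.PowerTensor, labels: dict, subject: str, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject-level contrast and condition-mean rows from a z tensor."""
    masks = _condition_masks(z.events, labels)
    effect_rows = []
    cond_rows = []
    for band_name in config.bands:
        band = spec.DEFAULT_BANDS[band_name]
        bv = spec.band_power(z, band)
        for contrast, (ca, cb) in CONTRAST_CONDITIONS.items():
            effect_rows.append(
                st.build_contrast(
                    bv, masks[ca], masks[cb], z.channels, subject, contrast,
                    band_name, region=config.region,
                )
            )
        for cond, mask in masks.items():
            if not mask.any():
                continue
            for hemi in ("L", "R"):
                sel = (z.channels["hemisphere"] == hemi) & (
                    z.channels["region"] == config.region
                )
                if not sel.any():
                    continue
                vals = bv[np.ix_(mask, sel.to_numpy())]
                cond_rows.append(
                    {
                        "subject": subject,
                        "hemisphere": hemi,
                        "band": band_name,
                        "condition": cond,
                        "value": float(np.nanmean(vals)),
                    }
                )
    return pd.concat(effect_rows, ignore_index=True), pd.DataFrame(cond_rows)


def _narrowband_rows(
    power: spec.PowerTensor, masks: dict, subject: str, config: RunConfig
) -> pd.DataFrame:
    """Robust 1/f fits of per-electrode remembered / forgotten mean spectra.

    Skipped (empty table) when the analysis grid has fewer than 10
    frequencies inside the 1-50 Hz fitting range.
    """
    rows = []
    n_in_range = int(np.sum((power.freqs >= 1.0) & (power.freqs <= 50.0)))
    if n_in_range < 10:
        return pd.DataFrame(rows)
    hip = (power.channels["region"] == config.region).to_numpy()
    for cond in ("remembered", "forgotten"):
        mask = masks[cond]
        if not mask.any():
            continue
        freqs, spectra = spec.mean_spectrum(power, mask, freq_range=(1.0, 50.0))
        for c in np.flatnonzero(hip):
            y = spectra[c]
            if not np.all(np.isfinite(y)):
                continue
            res = st.narrowband_detect(freqs, y)
            near_osc = np.any(
                np.abs(np.log2(res.flagged / config.neural.osc_freq_hz)) <= 0.35
            ) if res.flagged.size else False
            rows.append(
                {
                    "subject": subject,
                    "channel": power.channels["channel"].iloc[c],
                    "hemisphere": power.channels["hemisphere"].iloc[c],
                    "condition": cond,
                    "slope": res.slope,
                    "n_flagged": int(res.flagged.size),
                    "osc_flagged": bool(near_osc),
                }
            )
    return pd.DataFrame(rows)


def _subject_features(sets: dict, labels: dict, config: RunConfig) -> dict:
    """z-power features on the dedicated 10+10 decoding grid."""
    grid = spec.ExplicitGrid(tuple(clf.classifier_frequencies("both")), config.grid.wavenumber)
    power = spec.event_power(sets, grid)
    z = spec.log_and_zscore(power)
    enc = (z.events["event"] == "encoding").to_numpy()
    enc_events = z.events[enc].reset_index(drop=True)
    enc_labels = enc_events["object_id"].map(labels).to_numpy()
    out = {}
    for freq_set in config.decode_freq_sets:
        fsel = np.isin(
            np.round(z.freqs, 9), np.round(clf.classifier_frequencies(freq_set), 9)
        )
        out[freq_set] = clf.build_features(
            z.values[enc][:, :, fsel],
            enc_events,
            enc_labels,
            z.freqs[fsel],
            z.channels,
            fold_by="trial",
        )
    return out


def run_subjects(config: RunConfig) -> list[SubjectResult]:
    return [run_subject(config, i) for i in range(config.n_subjects)]


def cohort_stats(results: list[SubjectResult], config: RunConfig) -> dict:
    """Group-level battery over per-subject results (the run report body)."""
    effects = pd.concat([r.effects for r in results], ignore_index=True)
    cond_means = pd.concat([r.condition_means for r in results], ignore_index=True)

    report: dict = {
        "n_subjects": len(results),
        "seed": config.seed,
        "behavioral": {r.subject: r.behavioral for r in results},
        "mean_accuracy": float(
            np.mean([r.behavioral["mean_accuracy"] for r in results])
        ),
        "rejection_fraction": float(
            np.mean([r.rejection["fraction_excluded"].mean() for r in results])
        ),
        "group_tests": {},
        "effect_table": effects.to_dict("records"),
    }

    n_band_tests = len(config.bands) * 2  # Bonferroni family: bands x hemispheres
    for contrast in effects["contrast"].unique():
        for band in config.bands:
            for hemi in ("L", "R"):
                sub = effects.query(
                    "contrast == @contrast and band == @band and hemisphere == @hemi"
                )["value"]
                if len(sub) < 2 or sub.std(ddof=1) == 0:
                    continue
                t, dof, p = st.group_ttest(sub.to_numpy())
                report["group_tests"][f"{contrast}:{band}:{hemi}"] = {
                    "t": t,
                    "dof": dof,
                    "p": p,
                    "p_bonferroni": min(p * n_band_tests, 1.0),
                    "n": int(len(sub)),
                }

    # hemisphere x condition (memory vs navigation contrast values) ANOVA
    lat = effects.query("band == 'low_theta' and contrast in ('memory', 'navigation')")
    try:
        report["laterality_anova"] = st.laterality_anova(lat, factor_b="contrast")
    except ValueError as e:  # degenerate small cohorts
        report["laterality_anova"] = {"error": str(e)}

    # variant ANOVAs on condition-level values
    for name, conds in (
        ("hemisphere_x_memory_success", ("remembered", "forgotten")),
        ("hemisphere_x_navigation_state", ("navigation", "baseline")),
    ):
        sub = cond_means.query("band == 'low_theta' and condition in @conds")
        try:
            report[name] = st.laterality_anova(sub, factor_b="condition")
        except ValueError as e:
            report[name] = {"error": str(e)}

    nb = pd.concat([r.narrowband for r in results], ignore_index=True)
    if len(nb):
        report["narrowband"] = {
            "mean_slope": float(nb["slope"].mean()),
            "osc_flag_rate": {
                cond: float(g["osc_flagged"].mean())
                for cond, g in nb.groupby("condition")
            },
        }

    if config.decode:
        report["decoding"] = _decoding_stats(results, config)

    report["ground_truth"] = _ground_truth_comparison(results, report)
    return report


def _decoding_stats(results: list[SubjectResult], config: RunConfig) -> dict:
    out: dict = {}
    rng_seed = np.random.SeedSequence(entropy=config.seed, spawn_key=(10_000,))
    for freq_set in config.decode_freq_sets:
        aucs, nulls = [], []
        for r in results:
            fm = r.features.get(freq_set)
            if fm is None:
                continue
            res = clf.crossval_auc(fm, config.penalty_c)
            aucs.append(res.auc)
            if config.n_shuffles:
                child = np.random.SeedSequence(
                    entropy=config.seed, spawn_key=(10_001, hash(r.subject) % 2**16)
                )
                nulls.append(
                    clf.shuffle_null(fm, config.n_shuffles, config.penalty_c, seed=child)
                )
        entry = {
            "mean_auc": float(np.mean(aucs)),
            "auc_per_subject": [float(a) for a in aucs],
        }
        if len(aucs) >= 2 and np.std(aucs, ddof=1) > 0:
            t, dof, p = st.group_ttest(np.asarray(aucs) - 0.5)
            entry["t_vs_chance"] = {"t": t, "dof": dof, "p": p}
        if nulls:
            entry["permutation_p"] = clf.cohort_permutation_p(
                np.asarray(aucs), np.vstack(nulls)
            )
        out[freq_set] = entry
    return out


def _ground_truth_comparison(results: list[SubjectResult], report: dict) -> dict:
    """Planted gains vs recovered low-theta contrast significance."""
    neural = results[0].neural
    planted = {
        "memory:L": neural.left_memory_gain > 1,
        "memory:R": neural.right_memory_gain > 1,
        "navigation:L": neural.left_nav_gain > 1,
        "navigation:R": neural.right_nav_gain > 1,
    }
    recovered = {}
    for key, was_planted in planted.items():
        contrast, hemi = key.split(":")
        gt = report["group_tests"].get(f"{contrast}:low_theta:{hemi}")
        recovered[key] = {
            "planted": was_planted,
            "significant": bool(gt and gt["p"] < 0.05 and gt["t"] > 0),
        }
    return recovered


def subset_filter(
    results: list[SubjectResult],
    criteria: str | None = None,
    predicate=None,
) -> list[SubjectResult]:
    """Filter a cohort by montage metadata before regenerating the report.

    ``criteria='bilateral'`` keeps subjects with hippocampal channels in both
    hemispheres; ``criteria='exclude_soz_ipsilateral'`` drops each subject's
    effect/condition rows for hemispheres containing a seizure-onset-zone
    channel; ``predicate`` is an arbitrary callable on SubjectResult.
    An empty resulting cohort raises.
    """
    out: list[SubjectResult] = []
    for r in results:
        if predicate is not None and not predicate(r):
            continue
        if criteria == "bilateral":
            hip = r.channels[r.channels["region"] == "hippocampus"]
            if not {"L", "R"} <= set(hip["hemisphere"]):
                continue
            out.append(r)
        elif criteria == "exclude_soz_ipsilateral":
            soz_hemis = set(r.channels.loc[r.channels["soz"], "hemisphere"])
            if soz_hemis:
                r = dataclasses.replace(
                    r,
                    effects=r.effects[~r.effects["hemisphere"].isin(soz_hemis)],
                    condition_means=r.condition_means[
                        ~r.condition_means["hemisphere"].isin(soz_hemis)
                    ],
                )
            if len(r.effects) == 0:
                continue
            out.append(r)
        else:
            out.append(r)
    if not out:
        raise ValueError("empty cohort after filtering")
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Full deterministic run: simulate -> score -> preprocess -> spectral ->
    stats (-> classify); optionally write the report JSON and TSV tables."""
    results = run_subjects(config)
    report = cohort_stats(results, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
        effects = pd.concat([r.effects for r in results], ignore_index=True)
        effects.to_csv(out / "subject_effects.tsv", sep="\t", index=False)
        rej = pd.concat(
            [r.rejection.assign(subject=r.subject) for r in results], ignore_index=True
        )
        rej.to_csv(out / "rejection_report.tsv", sep="\t", index=False)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
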