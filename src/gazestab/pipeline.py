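"""End-to-end orchestration: cohort simulation, analysis, comparison tables.

A :class:`RunConfig` describes a cohort design (conditions x animals) and all
seeds; :func:`run_pipeline` turns it into trial files, a metrics table,
condition summaries and a stats table, all deterministic for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .group_stats import kruskal_nemenyi, paired_signed_rank, rank_sum, summarize_condition
from .response_metrics import AnalysisConfig, analyze_trial
from .synthetic_data import ResponseModel, StimulusSpec, Trial, TrialMeta, generate_response, generate_stimulus
from .trial_io import metrics_frame, write_trial

__all__ = [
    "CohortCondition",
    "RunConfig",
    "run_pipeline",
    "make_fixtures",
    "compare_conditions",
    "SUMMARY_COLUMNS",
    "STATS_COLUMNS",
    "DESIGN_COLUMNS",
]

SUMMARY_COLUMNS = (
    "treatment",
    "light",
    "frequency",
    "n",
    "median_gain",
    "circ_median_phase_deg",
    "median_epsilon",
    "sem_epsilon",
)

STATS_COLUMNS = ("comparison", "test", "statistic", "p", "n")

DESIGN_COLUMNS = ("trial_id", "animal_id", "treatment", "light", "frequency")


@dataclass(frozen=True)
class CohortCondition:
    """One cell of the cohort design with its generative response parameters."""

    treatment: str
    light: str
    frequency: float
    gain: float
    phase: float
    n_animals: int = 8
    wingbeat_amp: float = 2.0
    wobble_amp: float = 0.5
    noise_sd: float = 0.5
    gain_jitter_sd: float = 0.0
    phase_jitter_sd: float = 0.0


@dataclass
class RunConfig:
    amplitude: float = 30.0
    n_cycles: int = 8
    sample_rate: float = 1200.0
    ramp_endpoints: bool = True
    seed: int = 0
    conditions: list[CohortCondition] = field(default_factory=list)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def validate(self) -> None:
        if not self.conditions:
            raise ValueError("config defines zero conditions/trials")
        if any(c.n_animals < 1 for c in self.conditions):
            raise ValueError("every condition needs n_animals >= 1")
        # instantiating the spec runs its own validation
        for c in self.conditions:
            StimulusSpec(c.frequency, self.amplitude, self.n_cycles,
                         self.sample_rate, self.ramp_endpoints)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analysis"]["psd"] = asdict(self.analysis.psd)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        conds = [CohortCondition(**c) for c in d.pop("conditions", [])]
        analysis = d.pop("analysis", None)
        if analysis is not None:
            from .response_metrics import PsdConfig

            psd = analysis.pop("psd", None)
            analysis = AnalysisConfig(
                **analysis, **({"psd": PsdConfig(**psd)} if psd else {})
            )
        else:
            analysis = AnalysisConfig()
        return cls(conditions=conds, analysis=analysis, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _trial_seed(base_seed: int, cond_idx: int, animal_idx: int) -> int:
    """Stable per-trial seed derived from the run seed and design position."""
    ss = np.random.SeedSequence([int(base_seed), cond_idx, animal_idx])
    return int(ss.generate_state(1)[0])


def simulate_cohort(config: RunConfig) -> tuple[list[Trial], pd.DataFrame]:
    """Generate every trial of the design; returns trials plus the design table."""
    config.validate()
    trials: list[Trial] = []
    rows = []
    for ci, cond in enumerate(config.conditions):
        spec = StimulusSpec(
            cond.frequency, config.amplitude, config.n_cycles,
            config.sample_rate, config.ramp_endpoints,
        )
        stimulus = generate_stimulus(spec)
        for ai in range(cond.n_animals):
            seed = _trial_seed(config.seed, ci, ai)
            jit = np.random.default_rng(seed + 1)
            gain = max(cond.gain + jit.normal(0.0, cond.gain_jitter_sd), 0.0) \
                if cond.gain_jitter_sd else cond.gain
            phase = cond.phase + (jit.normal(0.0, cond.phase_jitter_sd)
                                  if cond.phase_jitter_sd else 0.0)
            model = ResponseModel(
                gain=gain, phase=phase,
                wingbeat_amp=cond.wingbeat_amp, wobble_amp=cond.wobble_amp,
                noise_sd=cond.noise_sd, seed=seed,
            )
            animal_id = f"{cond.treatment}_a{ai:02d}"
            trial_id = f"{cond.treatment}_{cond.light}_{cond.frequency:g}Hz_a{ai:02d}"
            meta = TrialMeta(
                frequency=cond.frequency, amplitude=config.amplitude,
                light_condition=cond.light, treatment=cond.treatment,
                animal_id=animal_id, trial_id=trial_id,
            )
            trials.append(generate_response(stimulus, model, spec, meta))
            rows.append(
                {
                    "trial_id": trial_id,
                    "animal_id": animal_id,
                    "treatment": cond.treatment,
                    "light": cond.light,
                    "frequency": cond.frequency,
                }
            )
    return trials, pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))


def compare_conditions(
    merged: pd.DataFrame, value: str = "epsilon", paired_on: str = "light"
) -> pd.DataFrame:
    """Build the tidy stats table from a metrics+design table.

    For each (treatment, frequency) cell with exactly two levels of
    ``paired_on`` sharing animals, a paired signed-rank test compares the two
    levels.  Across treatments (within light x frequency), two groups get a
    rank-sum test and three or more get Kruskal-Wallis plus Nemenyi pairwise
    rows.  Returns columns ``comparison, test, statistic, p, n``.
    """
    rows: list[dict] = []

    group_cols = [c for c in ("treatment", "frequency") if c != paired_on]
    for key, sub in merged.groupby(group_cols, sort=True):
        levels = sorted(sub[paired_on].unique())
        if len(levels) != 2:
            continue
        a = sub[sub[paired_on] == levels[0]].set_index("animal_id")[value]
        b = sub[sub[paired_on] == levels[1]].set_index("animal_id")[value]
        shared = a.index.intersection(b.index)
        label = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        if len(shared) >= 2:
            try:
                stat, p = paired_signed_rank(a.loc[shared], b.loc[shared])
            except ValueError:
                continue
            rows.append(
                {
                    "comparison": f"{label}: {levels[0]} vs {levels[1]} (paired)",
                    "test": "wilcoxon_signed_rank",
                    "statistic": stat,
                    "p": p,
                    "n": len(shared),
                }
            )
        else:
            stat, p = rank_sum(a.to_numpy(), b.to_numpy())
            rows.append(
                {
                    "comparison": f"{label}: {levels[0]} vs {levels[1]}",
                    "test": "wilcoxon_rank_sum",
                    "statistic": stat,
                    "p": p,
                    "n": len(sub),
                }
            )

    for (light, freq), sub in merged.groupby(["light", "frequency"], sort=True):
        treatments = sorted(sub["treatment"].unique())
        if len(treatments) < 2:
            continue
        groups = [sub[sub["treatment"] == t][value].to_numpy() for t in treatments]
        if len(treatments) == 2:
            stat, p = rank_sum(groups[0], groups[1])
            rows.append(
                {
                    "comparison": f"{light}/{freq:g}Hz: {treatments[0]} vs {treatments[1]}",
                    "test": "wilcoxon_rank_sum",
                    "statistic": stat,
                    "p": p,
                    "n": len(sub),
                }
            )
        else:
            h, p, pmat = kruskal_nemenyi(groups)
            rows.append(
                {
                    "comparison": f"{light}/{freq:g}Hz: {' vs '.join(treatments)}",
                    "test": "kruskal_wallis",
                    "statistic": h,
                    "p": p,
                    "n": len(sub),
                }
            )
            for i in range(len(treatments)):
                for j in range(i + 1, len(treatments)):
                    rows.append(
                        {
                            "comparison": f"{light}/{freq:g}Hz: {treatments[i]} vs {treatments[j]}",
                            "test": "nemenyi",
                            "statistic": float("nan"),
                            "p": pmat[i, j],
                            "n": len(groups[i]) + len(groups[j]),
                        }
                    )

    return pd.DataFrame(rows, columns=list(STATS_COLUMNS))


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Simulate, analyze and compare the whole cohort; write all artifacts.

    Writes ``trials/*.csv``, ``design.csv``, ``metrics.csv``, ``summaries.csv``,
    ``stats.csv``, the resolved config and a machine-readable ``run_log.json``.
    Returns the artifact paths plus in-memory tables.
    """
    t0 = _time.perf_counter()
    config.validate()
    outdir = Path(outdir)
    (outdir / "trials").mkdir(parents=True, exist_ok=True)

    trials, design = simulate_cohort(config)
    failures = []
    metrics = []
    for trial in trials:
        spec = StimulusSpec(
            trial.meta.frequency, config.amplitude, config.n_cycles,
            config.sample_rate, config.ramp_endpoints,
        )
        write_trial(trial, outdir / "trials" / f"{trial.meta.trial_id}.csv", spec)
        try:
            metrics.append(analyze_trial(trial, spec, config.analysis))
        except ValueError as exc:
            failures.append({"trial_id": trial.meta.trial_id, "error": str(exc)})
    if failures:
        (outdir / "failures.json").write_text(json.dumps(failures, indent=2))
        raise RuntimeError(
            f"{len(failures)} trial(s) failed analysis; see failures.json"
        )

    mframe = metrics_frame(metrics, design["trial_id"])
    merged = mframe.merge(design, on="trial_id")

    summaries = []
    metric_by_id = dict(zip(design["trial_id"], metrics))
    for (treatment, light, freq), sub in merged.groupby(
        ["treatment", "light", "frequency"], sort=True
    ):
        summary = summarize_condition(
            [metric_by_id[tid] for tid in sub["trial_id"]],
            labels={"treatment": treatment, "light": light, "frequency": freq},
        )
        summaries.append(
            {
                "treatment": treatment,
                "light": light,
                "frequency": freq,
                "n": summary.n,
                "median_gain": summary.median_gain,
                "circ_median_phase_deg": summary.circ_median_phase,
                "median_epsilon": summary.median_epsilon,
                "sem_epsilon": summary.sem_epsilon,
            }
        )
    sframe = pd.DataFrame(summaries, columns=list(SUMMARY_COLUMNS))
    stats_frame = compare_conditions(merged)

    design.to_csv(outdir / "design.csv", index=False)
    mframe.to_csv(outdir / "metrics.csv", index=False, float_format="%.10g")
    sframe.to_csv(outdir / "summaries.csv", index=False, float_format="%.10g")
    stats_frame.to_csv(outdir / "stats.csv", index=False, float_format="%.10g")
    config.to_yaml(outdir / "config.resolved.yaml")
    log = {
        "config_hash": config.content_hash(),
        "gazestab_version": __version__,
        "numpy_version": np.__version__,
        "n_trials": len(trials),
        "elapsed_s": round(_time.perf_counter() - t0, 3),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return {
        "design": design,
        "metrics": mframe,
        "summaries": sframe,
        "stats": stats_frame,
        "log": log,
        "outdir": outdir,
    }


def fixture_config(seed: int = 0, n_animals: int = 4) -> RunConfig:
    """A small 2 treatments x 2 lights x 2 frequencies demo cohort (<= 32 trials).

    Generative regimes echo the qualitative picture of the tethered assay:
    intact animals in twilight respond with high gain near anti-phase, intact
    animals in the dark at 2 Hz respond with phase pushed far off anti-phase,
    and clipped animals in the dark barely respond at all.
    """
    regimes = [
        # treatment, light, f,  gain, phase
        ("intact", "twilight", 2.0, 0.60, 177.6),
        ("intact", "dark", 2.0, 0.40, 302.4),
        ("intact", "twilight", 6.0, 0.50, 173.7),
        ("intact", "dark", 6.0, 0.50, 214.2),
        ("clipped", "twilight", 2.0, 0.55, 174.0),
        ("clipped", "dark", 2.0, 0.10, 20.0),
        ("clipped", "twilight", 6.0, 0.50, 127.8),
        ("clipped", "dark", 6.0, 0.10, 40.0),
    ]
    conditions = [
        CohortCondition(
            treatment=t, light=l, frequency=f, gain=g, phase=p,
            n_animals=n_animals, gain_jitter_sd=0.03, phase_jitter_sd=4.0,
        )
        for t, l, f, g, p in regimes
    ]
    return RunConfig(seed=seed, conditions=conditions)


def make_fixtures(seed: int = 0, outdir: str | Path | None = None) -> dict:
    """Generate the packaged example cohort; optionally write it to ``outdir``."""
    config = fixture_config(seed=seed)
    if outdir is not None:
        return run_pipeline(config, outdir)
    trials, design = simulate_cohort(config)
    metrics = []
    for trial in trials:
        spec = StimulusSpec(
            trial.meta.frequency, config.amplitude, config.n_cycles,
            config.sample_rate, config.ramp_endpoints,
        )
        metrics.append(analyze_trial(trial, spec, config.analysis))
    mframe = metrics_frame(metrics, design["trial_id"])
    return {
        "trials": trials,
        "design": design,
        "metrics": mframe.merge(design, on="trial_id"),
        "config": config,
    }
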