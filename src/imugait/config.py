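"""Pipeline configuration: typed defaults, validation, YAML round-trip.

Defaults follow the reference training setup: SVM penalty C = 2 with an
RBF kernel and gamma = "scale"; LSTM with sequence length 5, 128 hidden
units, a 32-unit FC layer, 200 epochs, batch 64; 200 Hz sampling.  The
``run_pipeline`` helper composes the whole chain — simulate, label, train
both classifiers, evaluate, plan — at a configurable (by default desk)
scale and writes every intermediate artifact to a working directory.
"""

from __future__ import annotations

import difflib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

log = logging.getLogger("imugait")

CONFIG_SCHEMA_VERSION = 1


@dataclass
class SvmConfig:
    C: float = 2.0
    gamma: str | float = "scale"
    tree_order: list[str] = field(
        default_factory=lambda: ["SD", "LW", "US", "DS", "USL", "DSL", "TL", "TR", "LS", "RS"]
    )


@dataclass
class LstmConfig:
    hidden: int = 128
    fc: int = 32
    epochs: int = 200
    batch: int = 64
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass
class PlannerConfig:
    A: float = 40.0
    f: float = 2.0
    form: str = "product"  # "product" or "simple"


@dataclass
class SimulateConfig:
    n_subjects: int = 5
    cycles_per_state: int = 6
    noise_sigma_gyro: float = 0.05
    noise_sigma_acc: float = 0.1
    cycle_period: float = 1.0


@dataclass
class PipelineConfig:
    schema_version: int = CONFIG_SCHEMA_VERSION
    sample_rate: float = 200.0
    sequence_length: int = 5
    seed: int = 0
    svm: SvmConfig = field(default_factory=SvmConfig)
    lstm: LstmConfig = field(default_factory=LstmConfig)
    planner: PlannerConfig = field(default_factory=PlannerConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return validate_config(raw)


class ConfigError(ValueError):
    """Aggregated configuration violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {v}" for v in violations))


_SECTIONS = {"svm": SvmConfig, "lstm": LstmConfig, "planner": PlannerConfig,
             "simulate": SimulateConfig}


def _check_unknown(raw: dict, valid: list[str], prefix: str, violations: list[str]) -> None:
    for key in raw:
        if key not in valid:
            hint = difflib.get_close_matches(key, valid, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            violations.append(f"unknown key {prefix}{key!r}{suffix}")


def validate_config(raw: dict | None) -> PipelineConfig:
    """Build a typed, defaulted config or raise all violations at once."""
    raw = dict(raw or {})
    violations: list[str] = []
    top_fields = [f.name for f in fields(PipelineConfig)]
    _check_unknown(raw, top_fields, "", violations)

    kwargs = {}
    for section, cls in _SECTIONS.items():
        sub = raw.get(section, {})
        if not isinstance(sub, dict):
            violations.append(f"section {section!r} must be a mapping")
            sub = {}
        names = [f.name for f in fields(cls)]
        _check_unknown(sub, names, f"{section}.", violations)
        kwargs[section] = cls(**{k: v for k, v in sub.items() if k in names})

    cfg = PipelineConfig(
        schema_version=raw.get("schema_version", CONFIG_SCHEMA_VERSION),
        sample_rate=raw.get("sample_rate", 200.0),
        sequence_length=raw.get("sequence_length", 5),
        seed=raw.get("seed", 0),
        **kwargs,
    )

    if cfg.sample_rate <= 0:
        violations.append("sample_rate must be positive")
    if cfg.sequence_length < 1:
        violations.append("sequence_length must be >= 1")
    if cfg.lstm.epochs < 1:
        violations.append("lstm.epochs must be >= 1")
    if cfg.lstm.batch < 1:
        violations.append("lstm.batch must be >= 1")
    if cfg.lstm.hidden < 1:
        violations.append("lstm.hidden must be >= 1")
    if cfg.svm.C <= 0:
        violations.append("svm.C must be positive")
    if cfg.planner.form not in ("product", "simple"):
        violations.append("planner.form must be 'product' or 'simple'")
    if cfg.simulate.n_subjects < 1:
        violations.append("simulate.n_subjects must be >= 1")
    if cfg.simulate.cycles_per_state < 1:
        violations.append("simulate.cycles_per_state must be >= 1")
    if violations:
        raise ConfigError(violations)
    return cfg


def desk_scale_config(seed: int = 0) -> PipelineConfig:
    """A configuration that runs the full pipeline in minutes on one CPU:
    LSTM hidden 32 / 30 epochs, few subjects, short bouts."""
    cfg = validate_config({})
    cfg.seed = seed
    cfg.lstm = LstmConfig(hidden=32, fc=32, epochs=30, batch=64, seed=seed)
    cfg.simulate = SimulateConfig(n_subjects=5, cycles_per_state=6)
    return cfg


def run_pipeline(config: PipelineConfig, workdir) -> dict:
    """Simulate -> label -> train both models -> evaluate -> plan.

    Writes every intermediate (streams, events, models, reports, plan) to
    ``workdir`` and returns the summary report dict.  Each stage logs its
    duration and failures abort with the stage name.
    """
    from . import events as ev
    from . import features, lstm, planner, svm, synthio
    from .evaluation import evaluate, subject_split

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.time()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.time() - self.t0
                report["stages"][name] = round(dt, 3)
                if exc is not None:
                    log.error("stage %s: failed after %.1fs: %s", name, dt, exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                log.info("stage %s: done in %.1fs", name, dt)

        return _Timer()

    sim = config.simulate
    spec = synthio.GaitCycleSpec(
        cycle_period=sim.cycle_period,
        noise_sigma_gyro=sim.noise_sigma_gyro,
        noise_sigma_acc=sim.noise_sigma_acc,
        sample_rate=config.sample_rate,
        seed=config.seed,
    )

    with stage("simulate"):
        dataset = synthio.generate_dataset(
            synthio.MOTION_STATES, sim.n_subjects, sim.cycles_per_state,
            seed=config.seed, spec=spec,
        )
        dataset.streams[0].to_csv(workdir / "stream_subject0_SD.csv")

    with stage("label"):
        # per-sample gait-phase labels for the LW bouts, from detected events
        lw = [i for i, s in enumerate(dataset.states) if s == "LW"]
        phase_data = []
        for i in lw:
            rep = ev.detect_events(dataset.streams[i])
            labels = ev.label_phases(rep.timeline, dataset.streams[i].n_samples)
            phase_data.append((i, rep.timeline, labels))
        phase_data[0][1].to_csv(workdir / "events_subject0_LW.csv")

    with stage("train-state"):
        X, y, g = dataset.sample_arrays()
        train_mask, test_mask = subject_split(g, max(sim.n_subjects - 1, 1))
        stats = features.fit_stats([X[train_mask]])
        stats.to_json(workdir / "channel_stats.json")
        Xs = features.standardize(X, stats)
        stride = 5  # thin the per-sample training set; test uses every sample
        tree = svm.fit_tree(
            svm.build_tree(tuple(config.svm.tree_order)),
            Xs[train_mask][::stride], y[train_mask][::stride],
            C=config.svm.C, gamma=config.svm.gamma,
        )
        tree.save(workdir / "svm_model")

    with stage("evaluate-state"):
        state_report = evaluate(y[test_mask], tree.predict(Xs[test_mask]),
                                tuple(config.svm.tree_order))
        state_report.to_json(workdir / "report_state.json")

    with stage("train-phase"):
        seqs, targs, groups = [], [], []
        for i, _tl, labels in phase_data:
            Xi = features.standardize(dataset.streams[i], stats)
            s_i, t_i = features.make_sequences(Xi, labels, n=config.sequence_length)
            seqs.append(s_i)
            targs.append(t_i)
            groups.append(np.full(len(s_i), dataset.subject_ids[i]))
        S = np.concatenate(seqs)
        T = np.concatenate(targs)
        G = np.concatenate(groups)
        tr, te = subject_split(G, max(sim.n_subjects - 1, 1))
        tcfg = lstm.TrainConfig(
            epochs=config.lstm.epochs, batch_size=config.lstm.batch,
            learning_rate=config.lstm.learning_rate, hidden_size=config.lstm.hidden,
            fc_size=config.lstm.fc, seed=config.lstm.seed,
        )
        params, head, losses = lstm.train(tcfg, S[tr], T[tr])
        lstm.save_model(workdir / "lstm_model", params, head, tcfg)

    with stage("evaluate-phase"):
        pred = lstm.predict_phase(params, head, S[te])
        phase_report = evaluate(T[te], pred, ev.EVENT_ORDER)
        phase_report.to_json(workdir / "report_phase.json")

    with stage("plan"):
        i, timeline, _labels = phase_data[-1]
        states = dataset.state_labels[i]
        assist = planner.plan(
            states, timeline, A=config.planner.A, f=config.planner.f,
            sample_rate=config.sample_rate, form=config.planner.form,
        )
        assist.to_csv(workdir / "plan.csv")

    report.update(
        {
            "state": {"accuracy": state_report.accuracy, "macro_f1": state_report.macro_f1,
                      "mcc": state_report.mcc},
            "phase": {"accuracy": phase_report.accuracy, "macro_f1": phase_report.macro_f1,
                      "mcc": phase_report.mcc},
            "n_assist_profiles": len(assist.profiles),
            "final_train_loss": losses[-1],
        }
    )
    with open(workdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
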