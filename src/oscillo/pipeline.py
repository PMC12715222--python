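"""End-to-end orchestration: simulate -> preprocess -> spectral/PAC ->
session aggregation -> behavior -> group statistics.

A run is driven by a :class:`RunConfig` (YAML-loadable), is deterministic
given its master seed, and writes a run directory containing tidy tables,
figures mirroring the usual presentation of extinction electrophysiology
(normalized spectra per condition, band-power dot plots, stage-wise gamma
summaries, freezing-by-block curves), a copy of the config, and a manifest
with a SHA-256 checksum per artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .behavior import FreezingParams, block_means, score_freezing
from .core import BANDS, ValidationError
from .pac import coupling_ratio, pac_for_condition
from .preprocess import preprocess_pipeline
from .session import segment, stage_of_trial, trial_index_of
from .simulate import (
    SessionDesign,
    SimulationConfig,
    generate_cohort,
)
from .spectral import (
    WelchParams,
    average_psds,
    band_power,
    normalize_to_baseline,
    welch_psd,
)
from .stats import compare_two_groups, factorial_compare

log = logging.getLogger("oscillo.pipeline")


@dataclass
class RunConfig:
    """Declarative description of a full pipeline run."""

    n_per_group: int = 5
    group_specs: dict = field(
        default_factory=lambda: {
            "control": {},
            "mutant": {"group_gain": {"*": {"low_gamma": 0.7}}},
        }
    )
    design: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    welch: dict = field(default_factory=dict)
    bands: tuple[str, ...] = ("theta", "low_gamma", "high_gamma")
    pac_phase_band: str = "theta"
    pac_amp_band: str = "low_gamma"
    pac_n_bins: int = 18
    freezing_profile: dict = field(
        default_factory=lambda: {"baseline": 0.2, "tone_*": 0.6, "iti_*": 0.4}
    )
    freezing: dict = field(default_factory=dict)
    target_hz: float = 1000.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.pop("version", None)  # stamp written by to_yaml, not a field
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["bands"] = list(d["bands"])
        d["version"] = __version__
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def analyze_animal(record, schedule, cfg: RunConfig) -> pd.DataFrame:
    """Spectral, PAC and freezing measures for one simulated animal."""
    wp = WelchParams(**cfg.welch)
    trace = record.trace
    if trace.sampling_rate_hz != cfg.target_hz:
        trace = preprocess_pipeline(trace, target_hz=cfg.target_hz)
    rows = []

    baseline_psd = average_psds([welch_psd(s, wp) for s in segment(trace, schedule, "baseline")])
    n_tones = len(schedule.select("tone_*"))
    per_interval: dict[str, list[tuple[int, str]]] = {"tone": [], "iti": []}
    psds: dict[str, object] = {}
    for cond in ("tone", "iti"):
        for iv in schedule.select(f"{cond}_*"):
            (seg,) = segment(trace, schedule, iv.label)
            psd = normalize_to_baseline(welch_psd(seg, wp), baseline_psd)
            psds[iv.label] = psd
            per_interval[cond].append((trial_index_of(iv.label), iv.label))

    for cond in ("tone", "iti"):
        stage_groups: dict[str, list] = {}
        for k, label in per_interval[cond]:
            stage = stage_of_trial(k, n_tones)
            stage_groups.setdefault("all", []).append(psds[label])
            if stage != "excluded":
                stage_groups.setdefault(stage, []).append(psds[label])
        for stage, plist in stage_groups.items():
            mean_psd = average_psds(plist)
            for band in cfg.bands:
                rows.append(
                    (record.animal_id, record.group, cond, stage,
                     f"{band}_power", band_power(mean_psd, BANDS[band]))
                )

    pac_tone = pac_for_condition(
        trace, schedule, "tone_*", cfg.pac_phase_band, cfg.pac_amp_band, cfg.pac_n_bins
    )
    pac_iti = pac_for_condition(
        trace, schedule, "iti_*", cfg.pac_phase_band, cfg.pac_amp_band, cfg.pac_n_bins
    )
    rows.append((record.animal_id, record.group, "tone", "all", "mi", pac_tone.mi))
    rows.append((record.animal_id, record.group, "iti", "all", "mi", pac_iti.mi))
    rows.append(
        (record.animal_id, record.group, "session", "all", "coupling_ratio",
         coupling_ratio(pac_tone, pac_iti))
    )

    if record.motion is not None:
        fp = FreezingParams(**cfg.freezing)
        freeze = score_freezing(record.motion, fp, schedule)
        tones = freeze[freeze["label"].str.match(r"tone_\d+$")]
        for label, pct in zip(tones["label"], tones["freezing_pct"]):
            k = trial_index_of(label)
            stage = stage_of_trial(k, n_tones)
            if stage != "excluded":
                rows.append(
                    (record.animal_id, record.group, "tone", stage, "freezing_pct", pct)
                )
        blocks = block_means(tones["freezing_pct"].to_numpy())
        for bi, val in enumerate(blocks, start=1):
            rows.append(
                (record.animal_id, record.group, "tone", f"block_{bi}", "freezing_pct", val)
            )
    return pd.DataFrame(
        rows, columns=["animal_id", "group", "condition", "stage", "measure", "value"]
    )


def gamma_cohort_measures(
    seed: int,
    n_per_group: int = 5,
    low_gamma_gain: float = 0.6,
    design: SessionDesign | None = None,
    base_config: SimulationConfig | None = None,
    bands: tuple[str, ...] = ("low_gamma", "high_gamma"),
) -> pd.DataFrame:
    """Per-animal baseline-normalized band powers for a two-group cohort.

    Simulates ``control`` vs ``attenuated`` (low-gamma amplitude scaled by
    ``low_gamma_gain`` in the attenuated group during tones and ITIs; the
    baseline period is left untouched so the baseline-normalization
    denominator stays comparable across groups and the manipulation is
    band-specific by construction), runs the
    spectral chain, and returns a tidy frame with columns ``group``,
    ``measure`` (band x tone/iti, e.g. ``low_gamma_power_tone``) and
    ``value`` (one row per animal x measure).  This is the core of the
    detection-power workflow: a lean path through simulate -> Welch ->
    baseline normalization -> band power, without PAC or behavior.
    """
    design = design or SessionDesign(baseline_s=20.0, n_tones=6, tone_s=10.0, iti_s=5.0)
    base = base_config or SimulationConfig(sampling_rate_hz=1000.0)
    specs = {
        "control": {},
        "attenuated": {
            "group_gain": {
                "tone": {"low_gamma": low_gamma_gain},
                "iti": {"low_gamma": low_gamma_gain},
            }
        },
    }
    cohort, schedule = generate_cohort(n_per_group, specs, design, seed, base)
    wp = WelchParams()
    rows = []
    for rec in cohort:
        baseline_psd = average_psds(
            [welch_psd(s, wp) for s in segment(rec.trace, schedule, "baseline")]
        )
        for cond in ("tone", "iti"):
            psds = [
                normalize_to_baseline(welch_psd(s, wp), baseline_psd)
                for s in segment(rec.trace, schedule, f"{cond}_*")
            ]
            mean_psd = average_psds(psds)
            for band in bands:
                rows.append(
                    (rec.group, f"{band}_power_{cond}",
                     band_power(mean_psd, BANDS[band]))
                )
    return pd.DataFrame(rows, columns=["group", "measure", "value"])


def _figures(outdir: Path, table: pd.DataFrame) -> list[Path]:
    written = []

    def save(fig, name):
        p = outdir / name
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)

    bands = sorted(
        m for m in table["measure"].unique() if m.endswith("_power")
    )
    sub = table[(table["stage"] == "all") & table["measure"].isin(bands)]
    if not sub.empty:
        fig, axes = plt.subplots(1, len(bands), figsize=(3 * len(bands), 3), squeeze=False)
        for ax, band in zip(axes[0], bands):
            s = sub[sub["measure"] == band]
            for gi, (group, g) in enumerate(s.groupby("group")):
                for ci, (condlab, c) in enumerate(g.groupby("condition")):
                    xs = np.full(len(c), gi + 0.3 * ci)
                    ax.plot(xs, c["value"], "o", ms=4,
                            label=f"{group}/{condlab}" if band == bands[0] else None)
            ax.set_title(band.replace("_power", ""))
            ax.set_ylabel("norm. band power")
            ax.set_xticks([])
        axes[0][0].legend(fontsize=6)
        fig.tight_layout()
        save(fig, "band_power_dots.png")

    stages = ["early", "intermediate", "late"]
    sub = table[table["stage"].isin(stages) & table["measure"].isin(bands)]
    if not sub.empty:
        fig, axes = plt.subplots(1, len(bands), figsize=(3 * len(bands), 3), squeeze=False)
        for ax, band in zip(axes[0], bands):
            s = sub[(sub["measure"] == band) & (sub["condition"] == "tone")]
            for group, g in s.groupby("group"):
                means = [g.loc[g["stage"] == st, "value"].mean() for st in stages]
                ax.plot(range(3), means, "o-", label=group)
            ax.set_xticks(range(3), stages, fontsize=6)
            ax.set_title(band.replace("_power", ""))
        axes[0][0].legend(fontsize=6)
        fig.tight_layout()
        save(fig, "stagewise_band_power.png")

    blocks = table[table["stage"].str.startswith("block_") & (table["measure"] == "freezing_pct")]
    if not blocks.empty:
        fig, ax = plt.subplots(figsize=(4, 3))
        blocks = blocks.assign(block=blocks["stage"].str.removeprefix("block_").astype(int))
        for group, g in blocks.groupby("group"):
            m = g.groupby("block")["value"].mean()
            ax.plot(m.index, m.values, "o-", label=group)
        ax.set_xlabel("5-trial block")
        ax.set_ylabel("freezing (%)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        save(fig, "freezing_by_block.png")
    return written


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> Path:
    """Execute the full analysis and write the run directory.

    Returns the output directory path.  Raises with the failing stage named
    and writes a partial manifest when a stage aborts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stage = "config"
    try:
        cfg.to_yaml(outdir / "config.yaml")
        artifacts.append(outdir / "config.yaml")

        stage = "simulate"
        design = SessionDesign(**cfg.design)
        base = SimulationConfig(**{"sampling_rate_hz": cfg.target_hz, **cfg.simulation})
        log.info("simulating cohort: %d per group, seed %d", cfg.n_per_group, cfg.seed)
        cohort, schedule = generate_cohort(
            cfg.n_per_group, cfg.group_specs, design, cfg.seed, base,
            freezing_profile=cfg.freezing_profile,
        )
        schedule.to_csv(outdir / "schedule.csv")
        artifacts.append(outdir / "schedule.csv")

        stage = "analyze"
        tables = [analyze_animal(rec, schedule, cfg) for rec in cohort]
        table = pd.concat(tables, ignore_index=True)
        table.to_csv(outdir / "cohort_measures.csv", index=False)
        artifacts.append(outdir / "cohort_measures.csv")

        stage = "stats"
        groups = sorted(table["group"].unique())
        reports = []
        stat_scope = table[table["stage"] == "all"]
        for (measure, cond), sub in stat_scope.groupby(["measure", "condition"]):
            if len(groups) != 2:
                break
            x = sub.loc[sub["group"] == groups[0], "value"].to_numpy()
            y = sub.loc[sub["group"] == groups[1], "value"].to_numpy()
            if len(x) < 3 or len(y) < 3:
                continue
            rep = compare_two_groups(x, y)
            reports.append(
                {"measure": measure, "condition": cond, "test": rep.test_name,
                 "statistic": rep.statistic, "p_value": rep.p_value,
                 "mean_" + groups[0]: float(x.mean()), "mean_" + groups[1]: float(y.mean())}
            )
        pd.DataFrame(reports).to_csv(outdir / "group_tests.csv", index=False)
        artifacts.append(outdir / "group_tests.csv")

        power_tbl = table[
            table["measure"].str.endswith("_power") & (table["stage"] == "all")
        ]
        if len(groups) == 2 and not power_tbl.empty:
            fact = factorial_compare(power_tbl, factors=("group", "measure"))
            fact["anova"].to_csv(outdir / "anova.csv")
            fact["contrasts"].to_csv(outdir / "contrasts.csv", index=False)
            artifacts += [outdir / "anova.csv", outdir / "contrasts.csv"]

        stage = "figures"
        artifacts += _figures(outdir, table)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        partial = {
            "failed_stage": stage,
            "error": str(exc),
            "artifacts": {p.name: _sha256(p) for p in sorted(artifacts) if p.exists()},
        }
        (outdir / "manifest.json").write_text(json.dumps(partial, indent=2))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return outdir
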