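"""End-to-end pipeline: generate a corpus, run every analysis stage, and
write a diff-able Markdown report with CSV/JSON sidecars.

Stages run in isolation: a failing stage is recorded in the report and
later stages that do not depend on it still run.  One global seed fans
out to per-stage child seeds through a fixed stage-name hash, so adding a
stage never perturbs the randomness of earlier ones.  Reports contain no
timestamps; identical config + seed gives byte-identical report bodies.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .dynamics import run_scenarios
from .errors import RumorDynError
from .lifecycle import (
    IntensitySeries,
    compute_durations,
    compute_transition_rates,
    detect_lifecycle_times,
    hijack_spread_relation,
    stage_levels,
)
from .records import corpus_to_frame, write_csv, write_jsonl
from .synthetic import generate_corpus, generate_token_counts, generate_topic_shares
from .text_analytics import (
    classify_corpus_sentiment,
    stage_topic_clustering,
    top_k_word_frequencies,
    topic_shares,
)

__all__ = ["RunReport", "run_pipeline", "render_figures"]

logger = logging.getLogger(__name__)


def child_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed and the stage name."""
    return (int(seed) ^ zlib.crc32(stage.encode("utf-8"))) % (2**31)


@dataclass
class RunReport:
    """Everything a pipeline run produced, ready to be rendered."""

    config_echo: str
    seed: int
    sections: dict[str, dict] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    version: str = __version__

    def add(self, stage: str, **payload) -> None:
        self.sections[stage] = payload

    def fail(self, stage: str, error: Exception) -> None:
        self.failures[stage] = f"{type(error).__name__}: {error}"

    def to_markdown(self) -> str:
        lines = [
            "# rumordyn pipeline report",
            "",
            f"- package version: {self.version}",
            f"- seed: {self.seed}",
            "",
        ]
        for stage, payload in self.sections.items():
            lines.append(f"## {stage}")
            lines.append("")
            for key, value in payload.items():
                if isinstance(value, pd.DataFrame):
                    lines.append(value.to_markdown(floatfmt=".4f"))
                    lines.append("")
                elif isinstance(value, pd.Series):
                    lines.append(value.to_frame().to_markdown(floatfmt=".4f"))
                    lines.append("")
                else:
                    lines.append(f"- {key}: {value}")
            lines.append("")
        if self.failures:
            lines.append("## failed stages")
            lines.append("")
            for stage, msg in self.failures.items():
                lines.append(f"- {stage}: {msg}")
            lines.append("")
        if self.warnings:
            lines.append("## warnings")
            lines.append("")
            lines.extend(f"- {w}" for w in self.warnings)
            lines.append("")
        lines.append("## configuration echo")
        lines.append("")
        lines.append("```yaml")
        lines.append(self.config_echo.rstrip("\n"))
        lines.append("```")
        lines.append("")
        return "\n".join(lines)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute generate -> text analytics -> stage levels -> scenarios ->
    lifecycle and write all artifacts under ``out_dir``."""
    out = Path(out_dir if out_dir is not None else config.output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write-probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise RumorDynError(f"output directory {out} is not writable: {exc}") from exc

    echo = config.raw_text if config.raw_text is not None else "# defaults (no config file)"
    report = RunReport(config_echo=echo, seed=config.seed)
    corpus = None

    # -- generate ----------------------------------------------------------
    try:
        gen_cfg = config.generator.with_(seed=child_seed(config.seed, "generate"))
        corpus = generate_corpus(gen_cfg)
        write_jsonl(corpus, out / "records.jsonl")
        write_csv(corpus, out / "records.csv")
        report.add("generate", **{"corpus size": f"{len(corpus):,}", "records file": "records.csv"})
    except RumorDynError as exc:
        report.fail("generate", exc)

    # -- text analytics ----------------------------------------------------
    try:
        if corpus is None:
            raise RumorDynError("no corpus available (generate failed)")
        shares_t = topic_shares(corpus, k_topics=config.generator.k_topics)
        shares_t.rename_axis("topic").to_csv(out / "topic_shares.csv")
        shares_s = classify_corpus_sentiment(corpus, config.sentiment)
        shares_s.rename_axis("category").to_csv(out / "sentiment_shares.csv")
        seed_tok = child_seed(config.seed, "tokens")
        tokens = generate_token_counts(len(corpus), rng=seed_tok)
        ranked = top_k_word_frequencies(tokens, k=20)
        pd.DataFrame(ranked, columns=["token", "count"]).to_csv(out / "token_counts.csv", index=False)
        doc_topic = generate_topic_shares(corpus, rng=child_seed(config.seed, "doc-topic"))
        clust = stage_topic_clustering(
            doc_topic, [r.stage.value for r in corpus], seed=child_seed(config.seed, "clustering")
        )
        pd.DataFrame({
            "component_1": clust.coords[:, 0],
            "component_2": clust.coords[:, 1],
            "cluster": clust.labels,
            "stage": clust.stages,
        }).to_csv(out / "clustering.csv", index=False)
        report.add(
            "text analytics",
            topic_shares=shares_t,
            sentiment_shares=shares_s,
            **{"top token": f"{ranked[0][0]} ({ranked[0][1]:,})",
               "effective clusters": clust.n_effective_clusters},
        )
    except RumorDynError as exc:
        report.fail("text analytics", exc)

    # -- stage levels and hijack relation ---------------------------------
    try:
        if corpus is None:
            raise RumorDynError("no corpus available (generate failed)")
        levels = stage_levels(corpus)
        levels.to_csv(out / "stage_levels.csv")
        fit = hijack_spread_relation(corpus)
        pd.DataFrame({
            "hijack_index": fit.x_grid, "fitted": fit.fitted,
            "band_low": fit.band_low, "band_high": fit.band_high,
        }).to_csv(out / "hijack_fit.csv", index=False)
        report.add(
            "stage levels",
            stage_levels=levels,
            **{"hijack-spread slope": round(fit.slope, 4),
               "hijack-spread correlation": round(fit.correlation, 4)},
        )
    except RumorDynError as exc:
        report.fail("stage levels", exc)

    # -- intervention scenarios -------------------------------------------
    trajectories = None
    try:
        trajectories = run_scenarios(config.scenario_engine, list(config.scenarios))
        endpoints = pd.DataFrame({
            name: {col: traj[col][-1] for col in traj.columns}
            for name, traj in trajectories.items()
        }).T
        endpoints.index.name = "scenario"
        endpoints.to_csv(out / "scenario_endpoints.csv")
        for name, traj in trajectories.items():
            traj.to_csv(out / f"scenario_{name}.csv")
        report.add("scenarios", endpoints=endpoints.round(3))
    except RumorDynError as exc:
        report.fail("scenarios", exc)

    # -- lifecycle on the baseline believer curve -------------------------
    try:
        if trajectories is None:
            raise RumorDynError("no scenario trajectories (scenarios failed)")
        base = trajectories["baseline"]
        series = IntensitySeries(t=base.t, R=np.clip(base["believers"], 0.0, None))
        times = detect_lifecycle_times(series, config.lifecycle_thresholds)
        durations = compute_durations(times)
        payload = {
            "R_max": times.R_max,
            "landmarks": {"te": times.te, "tp": times.tp, "td": times.td, "tr": times.tr},
            "durations": {
                "d_emerge": durations.d_emerge,
                "d_growthdecline": durations.d_growthdecline,
                "d_decline": durations.d_decline,
                "d_total": durations.d_total,
            },
            "undefined": list(times.undefined),
        }
        if times.all_defined:
            rates = compute_transition_rates(series, times)
            payload["transition_rates"] = {"r_eg": rates.r_eg, "r_gd": rates.r_gd, "r_dr": rates.r_dr}
        (out / "lifecycle.json").write_text(json.dumps(payload, indent=2))
        report.add(
            "lifecycle",
            **{"landmarks": payload["landmarks"], "undefined": payload["undefined"] or "none"},
        )
    except RumorDynError as exc:
        report.fail("lifecycle", exc)

    (out / "report.md").write_text(report.to_markdown(), encoding="utf-8")
    return report


def render_figures(out_dir: str | Path) -> list[Path]:
    """Render the standard figure set from the CSV artifacts in ``out_dir``.

    Figures: topic-share and sentiment-share bars, stage trust/rumor bars,
    degree histogram, hijack scatter with fitted line and band, and the
    scenario believer/trust/panic panels.  Missing artifacts are skipped
    with a logged warning.  Returns the paths written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    written: list[Path] = []

    def save(fig, name: str) -> None:
        path = out / name
        fig.savefig(path, dpi=110, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    def have(*names: str) -> bool:
        missing = [n for n in names if not (out / n).exists()]
        if missing:
            logger.warning("skipping figure; missing artifacts: %s", ", ".join(missing))
            return False
        return True

    if have("topic_shares.csv"):
        shares = pd.read_csv(out / "topic_shares.csv", index_col=0)["share"]
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.bar([f"Topic {i}" for i in shares.index], 100 * shares.values, color="#4878b0")
        ax.set_ylabel("share (%)")
        ax.set_title("Topic distribution")
        save(fig, "fig_topic_shares.png")

    if have("sentiment_shares.csv"):
        shares = pd.read_csv(out / "sentiment_shares.csv", index_col=0)["share"]
        fig, ax = plt.subplots(figsize=(5.5, 3.2))
        ax.bar(shares.index, 100 * shares.values, color="#b04848")
        ax.set_ylabel("share (%)")
        ax.set_title("Sentiment distribution")
        ax.tick_params(axis="x", rotation=30)
        save(fig, "fig_sentiment_shares.png")

    if have("stage_levels.csv"):
        levels = pd.read_csv(out / "stage_levels.csv", index_col=0)
        fig, ax = plt.subplots(figsize=(5, 3.2))
        x = np.arange(len(levels))
        ax.bar(x - 0.18, levels["mean_trust"], width=0.36, label="trust")
        ax.bar(x + 0.18, levels["mean_rumor"], width=0.36, label="rumor")
        ax.set_xticks(x, levels.index)
        ax.set_ylabel("mean level")
        ax.set_title("Trust and rumor level by stage")
        ax.legend()
        save(fig, "fig_stage_levels.png")

    if have("records.csv"):
        frame = pd.read_csv(out / "records.csv")
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.hist(frame["degree"], bins=40, color="#6aa66a")
        ax.set_xlabel("node degree")
        ax.set_ylabel("frequency")
        ax.set_title("Network degree distribution")
        save(fig, "fig_degree_hist.png")

    if have("records.csv", "hijack_fit.csv"):
        frame = pd.read_csv(out / "records.csv")
        fitf = pd.read_csv(out / "hijack_fit.csv")
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.scatter(frame["hijack_index"], frame["spread_intensity"], s=6, alpha=0.35, color="#4878b0")
        ax.plot(fitf["hijack_index"], fitf["fitted"], color="crimson")
        ax.fill_between(fitf["hijack_index"], fitf["band_low"], fitf["band_high"],
                        color="pink", alpha=0.5)
        ax.set_xlabel("trust-hijack index")
        ax.set_ylabel("spread intensity")
        ax.set_title("Trust hijack vs rumor spread")
        save(fig, "fig_hijack_scatter.png")

    scenario_files = sorted(out.glob("scenario_*.csv"))
    scenario_files = [p for p in scenario_files if p.name != "scenario_endpoints.csv"]
    if scenario_files:
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
        for path in scenario_files:
            name = path.stem.removeprefix("scenario_")
            traj = pd.read_csv(path)
            for ax, col in zip(axes, ("believers", "trust", "panic")):
                ax.plot(traj["t"], traj[col], label=name)
        for ax, col in zip(axes, ("believers", "trust", "panic")):
            ax.set_xlabel("periods")
            ax.set_title(col)
        axes[0].legend(fontsize=7)
        save(fig, "fig_scenarios.png")
    else:
        logger.warning("skipping scenario figure; no scenario_*.csv artifacts")

    return written
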