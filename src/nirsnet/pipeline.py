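"""End-to-end driver: simulate -> preprocess -> ROI -> LI -> GC -> report.

Runs the whole analysis on a synthetic cohort and writes every stage's
tables plus a consolidated markdown report. All defaults follow the study
design: 10 Hz sampling, 0.02-0.2 Hz band, 5 s pre-task baseline, amplitude
read-out at 5 s, LI threshold 0.2 with f = 1, alpha = 0.05, GC threshold
sweep 0.15-0.45, 14 subjects with 4 sessions x 10 tasks. A run is a pure
function of its seed: identical config and seed give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import BlockAverage
from .granger import DEFAULT_THRESHOLDS, gc_heterotopic_matrix, group_edge_test, threshold_sweep
from .io import (
    write_block_average_tsv,
    write_events_tsv,
    write_ground_truth,
    write_snirf,
)
from .laterality import LIConfig, group_li_test, subject_li_table
from .montage import Montage, build_default_montage
from .preprocessing import bandpass, block_average, extract_epochs, intensity_to_od, od_to_hb
from .roi import amplitude_table, contrast_table, grand_average
from .schedule import CONDITIONS, generate_schedule
from .simulate import SimulationConfig, hb_to_intensity, simulate_subject

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "render_report"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    out_dir: str = "nirsnet_run"
    seed: int = 0
    n_subjects: int = 14
    n_sessions: int = 4
    tasks_per_session: int = 10
    conditions: tuple[str, ...] = CONDITIONS
    task_conditions: tuple[str, ...] = ("MV", "MO", "MOV")
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    band: tuple[float, float] = (0.02, 0.2)
    epoch_window: tuple[float, float] = (-5.0, 20.0)
    baseline: tuple[float, float] = (-5.0, 0.0)
    amplitude_time: float = 5.0
    li: LIConfig = field(default_factory=LIConfig)
    gc_window: tuple[float, float] = (0.0, 20.0)
    gc_max_lag: int = 20
    gc_threshold: float = 0.4
    gc_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    alpha: float = 0.05
    write_recordings: bool = True

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.integer):
                return int(obj)
            if isinstance(obj, np.floating):
                return float(obj)
            return obj

        return plain(dataclasses.asdict(self))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        from .laterality import LIConfig
        from .simulate import Coupling, NoiseConfig, SimulationConfig

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        li = raw.pop("li", None)
        kwargs = dict(raw)
        for key in ("conditions", "task_conditions", "band", "epoch_window",
                    "baseline", "gc_window", "gc_thresholds"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if sim is not None:
            noise = sim.pop("noise", None)
            couplings = sim.pop("couplings", None)
            if noise is not None:
                sim["noise"] = NoiseConfig(**noise)
            if couplings is not None:
                sim["couplings"] = tuple(Coupling(**c) for c in couplings)
            if "condition_amplitudes" in sim:
                sim["condition_amplitudes"] = {
                    k: tuple(v) for k, v in sim["condition_amplitudes"].items()
                }
            if "wavelengths" in sim:
                sim["wavelengths"] = tuple(sim["wavelengths"])
            kwargs["simulation"] = SimulationConfig(**sim)
        if li is not None:
            if "window" in li:
                li["window"] = tuple(li["window"])
            kwargs["li"] = LIConfig(**li)
        return cls(**kwargs)


@dataclass
class RunManifest:
    """Record of one completed run: config snapshot, seed, artifact paths."""

    config: dict
    seed: int
    version: str
    outputs: dict[str, list[str]]
    warnings: list[str]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _subject_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31 - 1)) for child in ss.spawn(n)]


def run_pipeline(config: PipelineConfig, montage: Montage | None = None) -> RunManifest:
    """Run every stage on a synthetic cohort and write all outputs.

    Per subject: simulate the Hb recording, push it through the forward
    optics and back (intensity -> OD -> Hb), bandpass, epoch, and average
    per condition. Then build the group amplitude table and contrasts, the
    laterality tables, and the per-condition GC matrices, group networks and
    threshold sweep. Returns a manifest listing every artifact.
    """
    montage = montage or build_default_montage()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, list[str]] = {}
    warnings: list[str] = []

    def record(stage: str, path: Path) -> Path:
        outputs.setdefault(stage, []).append(str(path))
        return path

    seeds = _subject_seeds(config.seed, config.n_subjects)
    tmin, tmax = config.epoch_window
    averages: dict[int, dict[str, BlockAverage]] = {}
    averages_gc: dict[int, dict[str, BlockAverage]] = {}

    for i, sub_seed in enumerate(seeds):
        logger.info("[simulate] subject %02d seed %d", i, sub_seed)
        try:
            schedule = generate_schedule(
                config.n_sessions, config.tasks_per_session, rng_seed=sub_seed,
                conditions=config.conditions,
            )
            sim = dataclasses.replace(config.simulation, rng_seed=sub_seed)
            ts, gt = simulate_subject(montage, schedule, sim)
            sub_dir = out / f"subject{i:02d}"
            sub_dir.mkdir(exist_ok=True)
            write_events_tsv(schedule, record("simulate", sub_dir / "events.tsv"))
            write_ground_truth(gt, record("simulate", sub_dir / "ground_truth.json"))
            if config.write_recordings:
                write_snirf(ts, record("simulate", sub_dir / "recording.snirf"),
                            subject_id=f"subject{i:02d}")

            raw = hb_to_intensity(ts, montage, sim)
            hb = od_to_hb(intensity_to_od(raw), montage, dpf=sim.dpf)
            filtered = bandpass(hb, *config.band)
            epochs = extract_epochs(filtered, schedule, tmin, tmax, baseline=config.baseline)
            if epochs.n_dropped:
                warnings.append(
                    f"subject {i}: dropped {epochs.n_dropped} truncated epoch(s)"
                )
            # GC needs the innovation noise that the narrow bandpass strips
            # out, so its block averages come from the unfiltered series.
            epochs_gc = extract_epochs(hb, schedule, tmin, tmax, baseline=config.baseline)
            averages[i] = {}
            averages_gc[i] = {}
            for cond in config.conditions:
                avg = block_average(epochs, cond)
                averages[i][cond] = avg
                averages_gc[i][cond] = block_average(epochs_gc, cond)
                write_block_average_tsv(
                    avg, record("preprocess", sub_dir / f"block_average_{cond}.tsv")
                )
        except Exception as exc:
            raise RuntimeError(
                f"stage simulate/preprocess failed for subject {i} "
                f"(out={config.out_dir})"
            ) from exc

    # --- ROI stage -------------------------------------------------------
    try:
        amps = amplitude_table(averages, t=config.amplitude_time)
        amps.to_csv(record("roi", out / "amplitudes.tsv"), sep="\t", index=False,
                    float_format="%.6g")
        right = tuple(montage.right_channels)
        pairs = [("MOV", "MO"), ("MOV", "MV"), ("MV", "MO")]
        contrasts = pd.concat(
            [contrast_table(amps, a, b, channels=right) for a, b in pairs],
            ignore_index=True,
        )
        contrasts.to_csv(record("roi", out / "contrasts.tsv"), sep="\t", index=False,
                         float_format="%.6g")
        for cond in config.conditions:
            ga = grand_average([averages[i][cond] for i in averages])
            write_block_average_tsv(ga, record("roi", out / f"grand_average_{cond}.tsv"))
    except Exception as exc:
        raise RuntimeError(f"stage roi failed (out={config.out_dir})") from exc

    # --- Laterality stage ------------------------------------------------
    try:
        li_rows, li_group_rows = [], []
        for cond in config.conditions:
            table = subject_li_table(
                {i: averages[i][cond] for i in averages}, montage, config.li
            )
            table.insert(0, "condition", cond)
            li_rows.append(table)
            group = group_li_test(table, config.li)
            group.insert(0, "condition", cond)
            li_group_rows.append(group)
        pd.concat(li_rows, ignore_index=True).to_csv(
            record("li", out / "li_subject.tsv"), sep="\t", index=False,
            float_format="%.6g",
        )
        pd.concat(li_group_rows, ignore_index=True).to_csv(
            record("li", out / "li_group.tsv"), sep="\t", index=False,
            float_format="%.6g",
        )
    except Exception as exc:
        raise RuntimeError(f"stage li failed (out={config.out_dir})") from exc

    # --- Granger network stage -------------------------------------------
    try:
        sweep_rows, edge_rows = [], []
        for cond in config.conditions:
            logger.info("[gcnet] condition %s", cond)
            matrices = []
            gc_tables = []
            for i in averages_gc:
                m = gc_heterotopic_matrix(
                    averages_gc[i][cond], montage, window=config.gc_window,
                    max_lag=config.gc_max_lag, subject=i,
                )
                matrices.append(m)
                t = m.table.copy()
                t.insert(0, "subject", i)
                gc_tables.append(t)
            gc_all = pd.concat(gc_tables, ignore_index=True)
            gc_all.insert(0, "condition", cond)
            gc_all.to_csv(record("gcnet", out / f"gc_values_{cond}.tsv"), sep="\t",
                          index=False, float_format="%.6g")
            net = group_edge_test(matrices, config.gc_threshold, alpha=config.alpha)
            nt = net.table.copy()
            nt.insert(0, "condition", cond)
            edge_rows.append(nt)
            sweep = threshold_sweep(matrices, config.gc_thresholds, alpha=config.alpha)
            sweep.insert(0, "condition", cond)
            sweep_rows.append(sweep)
        pd.concat(edge_rows, ignore_index=True).to_csv(
            record("gcnet", out / "network.tsv"), sep="\t", index=False,
            float_format="%.6g",
        )
        pd.concat(sweep_rows, ignore_index=True).to_csv(
            record("gcnet", out / "sweep.tsv"), sep="\t", index=False,
            float_format="%.6g",
        )
    except Exception as exc:
        raise RuntimeError(f"stage gcnet failed (out={config.out_dir})") from exc

    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        version=__version__,
        outputs=outputs,
        warnings=warnings,
    )
    manifest.save(out / "manifest.json")
    outputs.setdefault("manifest", []).append(str(out / "manifest.json"))
    return manifest


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.4g}") -> str:
    def fmt(v: object) -> str:
        if isinstance(v, float):
            return floatfmt.format(v)
        return str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "| " + " | ".join("---" for _ in df.columns) + " |"
    rows = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *rows])


def render_report(manifest: RunManifest, path: str | Path | None = None) -> str:
    """Render a consolidated markdown report from a completed run.

    Three sections: the channel amplitude contrasts, the group laterality
    summary per condition, and the causal-network edge counts across the
    threshold sweep (plus the edge list at the default threshold).
    """
    out = Path(manifest.config["out_dir"])

    def require(name: str) -> Path:
        p = out / name
        if not p.exists():
            raise FileNotFoundError(f"missing stage output {name}: rerun that stage")
        return p

    contrasts = pd.read_csv(require("contrasts.tsv"), sep="\t")
    li_group = pd.read_csv(require("li_group.tsv"), sep="\t")
    sweep = pd.read_csv(require("sweep.tsv"), sep="\t")
    network = pd.read_csv(require("network.tsv"), sep="\t")

    lines = [
        "# nirsnet run report",
        "",
        f"Seed {manifest.seed}, {manifest.config['n_subjects']} synthetic subjects, "
        f"nirsnet {manifest.version}.",
        "",
        "## HbO amplitude contrasts at "
        f"{manifest.config['amplitude_time']} s (right hemisphere)",
        "",
        _md_table(
            contrasts[["contrast", "channel", "t", "p", "sig_05", "sig_01"]]
        ),
        "",
        "## Group laterality (one-sample t vs LI threshold "
        f"{manifest.config['li']['li_threshold']})",
        "",
        _md_table(
            li_group[["condition", "pair", "mean_li", "t", "p", "lateralized"]]
        ),
        "",
        "## Causal network: edge counts by GC threshold",
        "",
        _md_table(sweep),
        "",
        f"## Causal network edges at threshold {manifest.config['gc_threshold']}",
        "",
    ]
    edges = network[network["edge"]]
    if edges.empty:
        lines.append("No directed pair exceeded the threshold at group level.")
    else:
        lines.append(
            _md_table(edges[["condition", "src", "dst", "mean_gc", "t", "p"]])
        )
    lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text
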