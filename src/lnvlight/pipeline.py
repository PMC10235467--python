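"""End-to-end pipeline: simulate -> analyze -> test -> report.

A single :class:`PipelineConfig` drives everything.  Its default parameter tables are
the study conditions being emulated: per-genotype baseline firing rates
(p12c 4.2, gl60j 3.6, cry-null 3.9, gl60j-cry-null 5.2, rh7-null 2.4 Hz), the
genotype x wavelength light-evoked fold-changes, the genotype x wavelength x intensity
arousal probabilities, and the per-condition cell counts.  Outputs are tab-separated
tables (per-cell, per-group, comparisons, arousal summaries) that are byte-identical
across reruns with the same master seed; each written table's SHA-256 checksum is
logged for provenance.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import behavior_analysis as ba
from . import ephys_analysis as ea
from . import stats_inference as si
from .synth_behavior import BehaviorGenotypeParams, PulseSchedule, simulate_dam_cohort
from .synth_ephys import EphysGenotypeParams, SweepProtocol, iter_ephys_cohort

logger = logging.getLogger(__name__)

CONTROL = "p12c"
GENOTYPES = ("p12c", "gl60j", "cry-null", "gl60j-cry-null", "rh7-null")
WAVELENGTHS = {"uv": 365, "violet": 405, "blue": 450, "red": 635}

#: group-mean baseline firing rates (Hz) by genotype
BASELINE_HZ = {
    "p12c": 4.2,
    "gl60j": 3.6,
    "cry-null": 3.9,
    "gl60j-cry-null": 5.2,
    "rh7-null": 2.4,
}

#: light-evoked FF fold-change by genotype x wavelength (nm)
FOLD_CHANGE = {
    "p12c": {365: 1.667, 405: 1.899, 450: 1.958, 635: 1.197},
    "gl60j": {365: 1.129, 405: 1.016, 450: 1.213, 635: 1.06},
    "cry-null": {365: 1.099, 405: 1.39, 450: 1.066, 635: 1.04},
    "gl60j-cry-null": {365: 1.328, 405: 0.994, 450: 1.026, 635: 0.981},
    "rh7-null": {365: 1.115, 405: 1.056, 450: 1.289, 635: 1.074},
}

#: post-stimulus persistence time constants (s); qualitative reconstructions of the
#: wavelength-ordered persistence (blue longest, red none), config-overridable
DECAY_TAU = {
    "p12c": {365: 6.0, 405: 12.0, 450: 25.0, 635: 0.0},
    **{
        g: {365: 3.0, 405: 5.0, 450: 8.0, 635: 0.0}
        for g in ("gl60j", "cry-null", "gl60j-cry-null", "rh7-null")
    },
}

#: recorded-cohort sizes (cells) per genotype x wavelength
EPHYS_N = {
    "p12c": {365: 13, 405: 13, 450: 16, 635: 16},
    "gl60j": {365: 13, 405: 15, 450: 16, 635: 18},
    "cry-null": {365: 19, 405: 9, 450: 22, 635: 15},
    "gl60j-cry-null": {365: 9, 405: 11, 450: 12, 635: 11},
    "rh7-null": {365: 10, 405: 10, 450: 13, 635: 10},
}

#: per-pulse arousal probability by genotype x wavelength x intensity (uW/cm2)
AROUSAL_PROB = {
    "p12c": {
        (365, 10.0): 0.8503, (405, 10.0): 0.6519, (450, 10.0): 0.6375, (635, 10.0): 0.7036,
        (365, 400.0): 0.7905, (405, 400.0): 0.7954, (450, 400.0): 0.748, (635, 400.0): 0.3611,
    },
    "gl60j": {
        (365, 10.0): 0.3379, (405, 10.0): 0.3132, (450, 10.0): 0.3147, (635, 10.0): 0.317,
        (365, 400.0): 0.7097, (405, 400.0): 0.7091, (450, 400.0): 0.6392, (635, 400.0): 0.2145,
    },
    "cry-null": {
        (365, 10.0): 0.8199, (405, 10.0): 0.5766, (450, 10.0): 0.4928, (635, 10.0): 0.5992,
        (365, 400.0): 0.7119, (405, 400.0): 0.7597, (450, 400.0): 0.4706, (635, 400.0): 0.3443,
    },
    "gl60j-cry-null": {
        (365, 10.0): 0.1705, (405, 10.0): 0.2189, (450, 10.0): 0.2268, (635, 10.0): 0.2641,
        (365, 400.0): 0.5701, (405, 400.0): 0.4067, (450, 400.0): 0.5631, (635, 400.0): 0.2023,
    },
    "rh7-null": {
        (365, 10.0): 0.4767, (405, 10.0): 0.4086, (450, 10.0): 0.1794, (635, 10.0): 0.6283,
        (365, 400.0): 0.48, (405, 400.0): 0.2372, (450, 400.0): 0.2961, (635, 400.0): 0.3132,
    },
}


def default_ephys_params() -> dict[str, EphysGenotypeParams]:
    return {
        g: EphysGenotypeParams(
            baseline_rate=BASELINE_HZ[g],
            fold_change=dict(FOLD_CHANGE[g]),
            decay_tau=dict(DECAY_TAU[g]),
        )
        for g in GENOTYPES
    }


def default_behavior_params() -> dict[str, BehaviorGenotypeParams]:
    return {g: BehaviorGenotypeParams(arousal_prob=dict(AROUSAL_PROB[g])) for g in GENOTYPES}


@dataclass
class PipelineConfig:
    """Declarative configuration for a full pipeline run."""

    mode: str = "both"  # ephys | behavior | both
    master_seed: int = 0
    outdir: Path | None = None
    genotypes: tuple[str, ...] = GENOTYPES
    wavelengths: tuple[int, ...] = (365, 405, 450, 635)
    intensities: tuple[float, ...] = (10.0, 400.0)
    control: str = CONTROL
    tail: str = "greater"  # alternative: control > mutant
    sampling_rate: float = 10_000.0
    n_flies: int = 32
    ephys_params: dict[str, EphysGenotypeParams] = field(default_factory=default_ephys_params)
    behavior_params: dict[str, BehaviorGenotypeParams] = field(
        default_factory=default_behavior_params
    )
    ephys_n: dict[str, dict[int, int]] = field(default_factory=lambda: {
        g: dict(EPHYS_N[g]) for g in GENOTYPES
    })
    protocol: SweepProtocol = field(default_factory=SweepProtocol)
    schedule: PulseSchedule = field(default_factory=PulseSchedule)

    def __post_init__(self) -> None:
        if self.mode not in ("ephys", "behavior", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for g in self.genotypes:
            if self.mode != "behavior" and g not in self.ephys_params:
                raise ValueError(f"no ephys parameters for genotype {g!r}")
            if self.mode != "ephys" and g not in self.behavior_params:
                raise ValueError(f"no behavior parameters for genotype {g!r}")
        if self.control not in self.genotypes:
            raise ValueError(f"control genotype {self.control!r} not in genotypes")
        if self.outdir is not None:
            self.outdir = Path(self.outdir)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config; unspecified fields keep the documented defaults.

    Recognized keys: mode, master_seed, outdir, genotypes, wavelengths, intensities,
    control, sampling_rate, n_flies, plus per-genotype overrides under
    ``baseline_hz``, ``fold_change`` (genotype -> {wavelength: k}), ``decay_tau`` and
    ``arousal_prob`` (genotype -> {"wavelength,intensity": p}).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    for key in ("mode", "master_seed", "outdir", "control", "sampling_rate", "n_flies"):
        if key in raw:
            kwargs[key] = raw[key]
    for key in ("genotypes", "wavelengths", "intensities"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    ephys = default_ephys_params()
    for g, hz in (raw.get("baseline_hz") or {}).items():
        ephys[g] = replace(ephys[g], baseline_rate=float(hz))
    for g, table in (raw.get("fold_change") or {}).items():
        ephys[g] = replace(ephys[g], fold_change={int(w): float(k) for w, k in table.items()})
    for g, table in (raw.get("decay_tau") or {}).items():
        ephys[g] = replace(ephys[g], decay_tau={int(w): float(t) for w, t in table.items()})
    kwargs["ephys_params"] = ephys
    behavior = default_behavior_params()
    for g, table in (raw.get("arousal_prob") or {}).items():
        probs = {}
        for key, p in table.items():
            w, intensity = str(key).split(",")
            probs[(int(w), float(intensity))] = float(p)
        behavior[g] = replace(behavior[g], arousal_prob=probs)
    kwargs["behavior_params"] = behavior
    return PipelineConfig(**kwargs)


def _write_tsv(df: pd.DataFrame, outdir: Path | None, name: str) -> None:
    if outdir is None:
        return
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / name
    df.to_csv(path, sep="\t", index=False)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    logger.info("wrote %s (%d rows, sha256 %s)", path, len(df), digest[:16])


def analyze_ephys_condition(
    config: PipelineConfig, genotype: str, wavelength: int
) -> list[ea.FFResult]:
    """Simulate and analyze one genotype x wavelength condition, cell by cell."""
    params = config.ephys_params[genotype]
    protocol = replace(config.protocol, wavelength=wavelength)
    n_cells = config.ephys_n.get(genotype, {}).get(wavelength, 10)
    cells: list[ea.FFResult] = []
    sweeps: list = []
    for trace, _truth in iter_ephys_cohort(
        params, genotype, n_cells, protocol, config.master_seed, config.sampling_rate
    ):
        sweeps.append(ea.detect_spikes(trace, protocol))
        if len(sweeps) == protocol.n_sweeps:
            cells.append(ea.combine_sweeps(sweeps))
            sweeps = []
    return cells


def run_ephys_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Full ephys arm: cohorts -> detection -> FF ratios -> groups -> comparisons.

    Returns (and writes, when ``config.outdir`` is set) four tables: ``per_cell``,
    ``group`` (mean +/- SEM per condition), ``comparisons`` (control vs each mutant
    per wavelength family, BH-adjusted within family) and ``baseline_zt`` (the
    descriptive baseline-vs-ZT correlation per genotype).
    """
    per_cell_rows = []
    group_rows = []
    comparison_results: list[si.TestResult] = []
    cells_by_condition: dict[tuple[str, int], list[ea.FFResult]] = {}
    for wavelength in config.wavelengths:
        for genotype in config.genotypes:
            cells = analyze_ephys_condition(config, genotype, wavelength)
            cells_by_condition[(genotype, wavelength)] = cells
            for c in cells:
                per_cell_rows.append(
                    {
                        "genotype": genotype,
                        "wavelength_nm": wavelength,
                        "cell_id": c.meta.cell_id,
                        "zt_hour": c.meta.zt_hour,
                        "ff_ratio": c.ratio,
                        "baseline_hz": c.baseline_rate,
                        **{f"post_bin_{i + 1}": c.post_bins[i] for i in range(c.post_bins.size)},
                    }
                )
            summary = ea.aggregate_group(cells, genotype, wavelength)
            group_rows.append(
                {
                    "genotype": genotype,
                    "wavelength_nm": wavelength,
                    "n": summary.n,
                    "mean_ff_ratio": summary.mean,
                    "sem": summary.sem,
                    "n_excluded": summary.n_excluded,
                }
            )
        # one FDR family per wavelength: control vs each mutant
        family = []
        ctrl = np.array([c.ratio for c in cells_by_condition[(config.control, wavelength)] if c.defined])
        for genotype in config.genotypes:
            if genotype == config.control:
                continue
            mut = np.array([c.ratio for c in cells_by_condition[(genotype, wavelength)] if c.defined])
            family.append(
                si.adaptive_two_sample_test(
                    ctrl, mut, tail=config.tail,
                    label=f"ff_ratio/{wavelength}nm/{config.control}-vs-{genotype}",
                )
            )
        comparison_results.extend(si.adjust_family(family))
    per_cell = pd.DataFrame(per_cell_rows)
    group = pd.DataFrame(group_rows)
    comparisons = _results_frame(comparison_results)
    baseline_zt_rows = []
    for genotype in config.genotypes:
        sub = per_cell[per_cell.genotype == genotype]
        if len(sub) >= 3 and sub.baseline_hz.std() > 0:
            r, p = sps.pearsonr(sub.zt_hour, sub.baseline_hz)
        else:
            r, p = np.nan, np.nan
        baseline_zt_rows.append(
            {"genotype": genotype, "n": len(sub), "pearson_r": r, "p_value": p}
        )
    baseline_zt = pd.DataFrame(baseline_zt_rows)
    out = {
        "per_cell": per_cell,
        "group": group,
        "comparisons": comparisons,
        "baseline_zt": baseline_zt,
    }
    for name, df in out.items():
        _write_tsv(df, config.outdir, f"ephys_{name}.tsv")
    return out


def run_behavior_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Full behavior arm: monitor synthesis -> sleep/arousal scoring -> comparisons.

    Returns ``summary`` (one row per genotype x wavelength x intensity with the nine
    per-pulse percentages, per-night means and the weighted total), and
    ``comparisons`` (control vs each mutant on the nine per-pulse percentages, one
    family per wavelength x intensity, BH-adjusted).
    """
    summary_rows = []
    comparison_results: list[si.TestResult] = []
    for wavelength in config.wavelengths:
        for intensity in config.intensities:
            pulse_pcts: dict[str, np.ndarray] = {}
            for genotype in config.genotypes:
                schedule = replace(config.schedule, wavelength=wavelength, intensity=intensity)
                records = simulate_dam_cohort(
                    config.behavior_params[genotype],
                    genotype,
                    config.n_flies,
                    schedule,
                    config.master_seed,
                )
                outcomes = pd.concat(
                    [ba.score_pulse_arousal(r, schedule) for r in records],
                    ignore_index=True,
                )
                summary = ba.summarize_arousal(outcomes, genotype, wavelength, intensity)
                pulse_pcts[genotype] = summary.per_pulse_pct["pct"].to_numpy()
                row = {
                    "genotype": genotype,
                    "wavelength_nm": wavelength,
                    "intensity_uw_cm2": intensity,
                    "total_pct_aroused": summary.total_pct,
                    "n_flies": config.n_flies,
                }
                for _, p in summary.per_pulse_pct.iterrows():
                    row[f"night{int(p.night)}_zt{int(p.pulse_zt)}_pct"] = p.pct
                for night, pct in summary.per_night_pct.items():
                    row[f"night{int(night)}_mean_pct"] = pct
                summary_rows.append(row)
            family = []
            for genotype in config.genotypes:
                if genotype == config.control:
                    continue
                family.append(
                    si.adaptive_two_sample_test(
                        pulse_pcts[config.control],
                        pulse_pcts[genotype],
                        tail=config.tail,
                        label=(
                            f"pct_aroused/{wavelength}nm/{intensity:g}uW/"
                            f"{config.control}-vs-{genotype}"
                        ),
                    )
                )
            comparison_results.extend(si.adjust_family(family))
    out = {
        "summary": pd.DataFrame(summary_rows),
        "comparisons": _results_frame(comparison_results),
    }
    for name, df in out.items():
        _write_tsv(df, config.outdir, f"behavior_{name}.tsv")
    return out


def run_all(config: PipelineConfig) -> dict[str, dict[str, pd.DataFrame]]:
    """Run the arms selected by ``config.mode``."""
    out: dict[str, dict[str, pd.DataFrame]] = {}
    if config.mode in ("ephys", "both"):
        out["ephys"] = run_ephys_pipeline(config)
    if config.mode in ("behavior", "both"):
        out["behavior"] = run_behavior_pipeline(config)
    return out


def _results_frame(results: list[si.TestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "comparison": r.label,
                "n_x": r.n_x,
                "n_y": r.n_y,
                "ad_p_x": r.ad_p_x,
                "ad_p_y": r.ad_p_y,
                "variance_p": r.variance_p,
                "test": r.test,
                "tail": r.tail,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "rejected_q0.1": r.rejected,
                "tier": r.tier,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "AROUSAL_PROB",
    "BASELINE_HZ",
    "CONTROL",
    "DECAY_TAU",
    "EPHYS_N",
    "FOLD_CHANGE",
    "GENOTYPES",
    "PipelineConfig",
    "WAVELENGTHS",
    "analyze_ephys_condition",
    "default_behavior_params",
    "default_ephys_params",
    "load_config",
    "run_all",
    "run_behavior_pipeline",
    "run_ephys_pipeline",
]
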