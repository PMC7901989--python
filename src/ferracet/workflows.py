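"""Report assembly for the two analysis workflows.

``run_culture_workflow`` takes a culture table and writes per-series
kinetics, per-condition Tukey comparisons across species, and a
stoichiometry/electron-balance summary per (species, condition).

``run_genome_workflow`` takes proteome FASTA files and writes a per-genome
multiheme-cytochrome summary, per-protein motif profiles, an optional gene
panel presence/absence matrix and optional assembly statistics.

Reports are plain CSV/TSV, written deterministically: identical inputs,
configuration and seed give byte-identical files.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import groupstats, hemescan, kinetics, stoichiometry
from .culture import CultureSeries, concentration_to_amount, read_culture_table

__all__ = ["run_culture_workflow", "run_genome_workflow"]


def _write_log(out_dir: Path, name: str, params: Mapping) -> None:
    lines = [f"{k} = {v}" for k, v in sorted(params.items())]
    (out_dir / name).write_text("\n".join(lines) + "\n")


def _stoichiometry_summary(series: Sequence[CultureSeries], volume_override: float | None):
    rows = []
    keys = sorted({(s.species, s.condition) for s in series})
    for species, condition in keys:
        treats = [
            s for s in series
            if s.species == species and s.condition == condition and s.mineral != "none"
        ]
        controls = [
            s for s in series
            if s.species == species and s.condition == condition and s.mineral == "none"
        ]
        if not treats or not controls:
            continue
        volume = volume_override or treats[0].culture_volume_mL

        def final_acetate_umol(group):
            return float(
                np.mean([concentration_to_amount(s.acetate_mM[-1], volume) for s in group])
            )

        control_ac = final_acetate_umol(controls)
        treat_ac = final_acetate_umol(treats)
        deficit = stoichiometry.acetate_deficit_electrons(control_ac, treat_ac)
        fe2_umol = float(
            np.mean(
                [
                    concentration_to_amount(kinetics.final_accumulation(s), volume)
                    for s in treats
                ]
            )
        )
        fe2_electrons = stoichiometry.electron_equivalents("Fe", fe2_umol)
        row = {
            "species": species,
            "condition": condition,
            "volume_mL": volume,
            "control_acetate_umol": control_ac,
            "treatment_acetate_umol": treat_ac,
            "diverted_electrons_umol": deficit.electrons,
            "deficit_clamped": deficit.clamped,
            "fe2_umol": fe2_umol,
            "fe2_electrons_umol": fe2_electrons,
            "diversion_efficiency": (
                stoichiometry.diversion_efficiency(fe2_electrons, deficit.electrons)
                if deficit.electrons > 0
                else np.nan
            ),
        }
        # theoretical acetate from the ethanol actually consumed, when measured
        etoh_consumed = [
            float(s.ethanol_mM[0] - s.ethanol_mM[-1])
            for s in controls
            if s.ethanol_mM is not None and not np.isnan(s.ethanol_mM[[0, -1]]).any()
        ]
        if etoh_consumed:
            consumed_umol = concentration_to_amount(max(np.mean(etoh_consumed), 0.0), volume)
            row["ethanol_consumed_umol"] = consumed_umol
            row["theoretical_acetate_umol"] = stoichiometry.theoretical_acetate(consumed_umol)
        else:
            row["ethanol_consumed_umol"] = np.nan
            row["theoretical_acetate_umol"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_culture_workflow(
    input_csv: str | Path,
    out_dir: str | Path,
    volume_mL: float | None = None,
    metric: str = "rate_mM_per_day",
    seed: int = 0,
    plot: bool = False,
) -> dict[str, Path]:
    """Kinetics + group statistics + electron balance for a culture table.

    ``metric`` names the per-replicate kinetics column compared across
    species by Tukey HSD (``rate_mM_per_day`` or ``final_fe2_mM``).
    Returns the mapping of report name to written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series = read_culture_table(input_csv)
    if not series:
        raise ValueError(f"no culture series found in {input_csv}")
    if any(s.n_timepoints < 2 for s in series):
        raise ValueError("every series needs at least 2 timepoints")

    report = kinetics.series_report(series)
    written: dict[str, Path] = {}
    kin_path = out_dir / "kinetics.csv"
    report.to_csv(kin_path, index=False)
    written["kinetics"] = kin_path

    # Tukey HSD across species, per condition, on treatment replicates
    for condition, sub in report[report["mineral"] != "none"].groupby("condition"):
        groups = {
            sp: vals[metric].dropna().to_list() for sp, vals in sub.groupby("species")
        }
        groups = {sp: v for sp, v in groups.items() if len(v) >= 2}
        if len(groups) < 2:
            warnings.warn(
                f"condition {condition!r}: fewer than 2 species with replicated "
                f"{metric!r}; Tukey test skipped",
                stacklevel=2,
            )
            continue
        try:
            comparison = groupstats.tukey_hsd(groups)
        except ValueError as exc:
            warnings.warn(f"condition {condition!r}: {exc}; Tukey test skipped", stacklevel=2)
            continue
        frame = comparison.to_frame()
        frame.insert(0, "condition", condition)
        frame["anova_F"] = comparison.f_statistic
        frame["anova_p"] = comparison.anova_p
        path = out_dir / f"tukey_{condition}.csv"
        frame.to_csv(path, index=False)
        written[f"tukey_{condition}"] = path

    stoich = _stoichiometry_summary(series, volume_mL)
    stoich_path = out_dir / "stoichiometry.csv"
    stoich.to_csv(stoich_path, index=False)
    written["stoichiometry"] = stoich_path

    if plot:
        written["plots"] = _plot_series(series, out_dir)

    _write_log(
        out_dir,
        "run_log.txt",
        {
            "workflow": "culture",
            "input": Path(input_csv).name,
            "volume_mL": volume_mL if volume_mL is not None else "per-series",
            "metric": metric,
            "seed": seed,
            "n_series": len(series),
        },
    )
    written["log"] = out_dir / "run_log.txt"
    return written


def _plot_series(series: Sequence[CultureSeries], out_dir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir = out_dir / "plots"
    plot_dir.mkdir(exist_ok=True)
    for s in series:
        fig, axes = plt.subplots(1, 3, figsize=(10, 3))
        if s.cell_density is not None:
            axes[0].semilogy(s.time_days, s.cell_density, "o-")
        axes[0].set(xlabel="time (days)", ylabel="cells/mL")
        axes[1].plot(s.time_days, s.acetate_mM, "D-", label="acetate")
        if s.ethanol_mM is not None:
            axes[1].plot(s.time_days, s.ethanol_mM, "^-", label="ethanol")
        axes[1].set(xlabel="time (days)", ylabel="mM")
        axes[1].legend(frameon=False)
        axes[2].plot(s.time_days, s.fe2_total_mM, "s-")
        axes[2].set(xlabel="time (days)", ylabel="Fe(II) mM")
        fig.suptitle(f"{s.species} {s.condition} {s.mineral} rep {s.replicate_id}")
        fig.tight_layout()
        name = "_".join(s.group_key).replace(" ", "-").replace("/", "-")
        fig.savefig(plot_dir / f"{name}.png", dpi=100)
        plt.close(fig)
    return plot_dir


def run_genome_workflow(
    proteomes: Mapping[str, str | Path],
    out_dir: str | Path,
    queries: str | Path | None = None,
    contigs: Mapping[str, str | Path] | None = None,
    tier: str = "primary_only",
    overlap_policy: str = "non_overlapping_greedy",
    thresholds: Mapping[str, float] | None = None,
    no_coverage: bool = False,
    backend: str = "builtin",
) -> dict[str, Path]:
    """Multiheme-cytochrome survey + optional panel screen + assembly stats.

    ``proteomes`` maps genome label to protein FASTA path; ``contigs``
    (optional) maps genome label to nucleotide FASTA.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    summary_rows = []
    panel_columns: dict[str, pd.Series] = {}
    for label in sorted(proteomes):
        fasta = proteomes[label]
        survey = hemescan.proteome_mhc_survey(fasta, tier=tier, overlap_policy=overlap_policy)
        profile_path = out_dir / f"profiles_{label}.tsv"
        survey.to_frame().to_csv(profile_path, sep="\t", index=False)
        written[f"profiles_{label}"] = profile_path
        summary_rows.append(
            {
                "genome": label,
                "n_proteins": survey.n_proteins,
                "predicted_MHCs": survey.n_multiheme,
                "multiheme_high": survey.n_multiheme_high,
            }
        )
        if queries is not None:
            results = hemescan.panel_presence(
                queries, fasta, thresholds=thresholds, no_coverage=no_coverage, backend=backend
            )
            panel_columns[label] = pd.Series(
                {r.gene: int(r.present) for r in results}, name=label
            )

    summary = pd.DataFrame(summary_rows)
    summary_path = out_dir / "mhc_summary.csv"
    summary.to_csv(summary_path, index=False)
    written["mhc_summary"] = summary_path

    if panel_columns:
        matrix = pd.DataFrame(panel_columns)
        matrix.index.name = "gene"
        panel_path = out_dir / "panel_matrix.csv"
        matrix.to_csv(panel_path)
        written["panel_matrix"] = panel_path

    if contigs:
        stats_rows = []
        for label in sorted(contigs):
            st = hemescan.assembly_stats(contigs[label])
            stats_rows.append(
                {
                    "genome": label,
                    "n_contigs": st.n_contigs,
                    "total_length_bp": st.total_length_bp,
                    "gc_percent": st.gc_percent,
                    "n50_bp": st.n50_bp,
                }
            )
        stats_path = out_dir / "assembly_stats.csv"
        pd.DataFrame(stats_rows).to_csv(stats_path, index=False)
        written["assembly_stats"] = stats_path

    _write_log(
        out_dir,
        "run_log_genome.txt",
        {
            "workflow": "genome",
            "tier": tier,
            "overlap_policy": overlap_policy,
            "no_coverage": no_coverage,
            "backend": backend,
            "genomes": ",".join(sorted(proteomes)),
        },
    )
    written["log"] = out_dir / "run_log_genome.txt"
    return written
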