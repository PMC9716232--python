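"""End-to-end analysis: panel → readouts → ratios → CES → report.

`analyze_panel` is the in-memory workhorse used by tests and scripts;
`run_pipeline` wraps it with file IO, stage-named error reporting and a run
log (config hash, seed, package version).  `render_report` summarizes a
results bundle as a plain-text report plus an ascending-CES bar plot with an
optional odds-ratio overlay from the variant registry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, config_hash, save_config
from .doseresponse import (
    FourPLFit,
    ec50_by_interpolation,
    ec50_ratio,
    fit_4pl,
    hemolysis_ternary_score,
)
from .errors import (
    DegenerateControlError,
    NoCrossingError,
    NoDataError,
    PipelineStageError,
    UnreliableFitError,
)
from .io import read_panel, write_table
from .registry import VariantRecord
from .scoring import (
    AssayRatioSet,
    CESResult,
    assay_correlations,
    classify_assay_ratio,
    score_panel,
    sensitivity_rank_shift,
    RankShift,
)
from .simulate import Panel
from .spr import daa_ratio as _daa_ratio
from .spr import binding_ratio as _binding_ratio
from .spr import equilibrium_response, fh_mediated_decay

__all__ = ["PanelResults", "analyze_panel", "run_pipeline", "render_report"]

_BAND_ASSAY_BY_COMPONENT = {
    "binding_vc": "binding", "daa_vc": "daa", "ca_cv": "ca", "ap_cv": "ap",
}


@dataclass
class PanelResults:
    """Everything the pipeline computes for one panel."""

    readouts: pd.DataFrame        # protein_id, assay, readout
    fits: pd.DataFrame            # per-protein 4PL fit table
    ratio_sets: list[AssayRatioSet]
    results: list[CESResult]      # ranked
    results_table: pd.DataFrame
    band_calls: pd.DataFrame
    correlations: pd.DataFrame
    rank_shift: RankShift

    def result_for(self, name: str) -> CESResult:
        for r in self.results:
            if r.variant_name == name:
                return r
        raise NoDataError(f"no result for '{name}'")


def _spr_readouts(panel: Panel, config: PipelineConfig) -> dict[str, dict[str, float]]:
    out = {}
    for name in panel.protein_names:
        eq = equilibrium_response(panel.binding[name], config.t_eq, config.eq_window)
        decay = fh_mediated_decay(panel.decay_fh[name], panel.decay_intrinsic,
                                  config.t_decay_read)
        out[name] = {"binding_eq_RU": eq, "fh_decay_RU": decay}
    return out


def _dose_fits(panel: Panel) -> dict[str, dict[str, FourPLFit]]:
    return {
        name: {assay: fit_4pl(curve) for assay, curve in panel.curves[name].items()}
        for name in panel.protein_names
    }


def analyze_panel(panel: Panel, config: PipelineConfig | None = None) -> PanelResults:
    """Run the full analysis on an in-memory panel.

    Per-variant ratios are formed strictly against the panel's own control
    (the pairwise same-batch comparison design).  Unreliable EC50 fits
    propagate as missing components, which fail the strict CES unless
    ``config.partial_ces`` allows renormalized partial scores.
    """
    config = config or PipelineConfig()
    control = panel.control_name

    readouts = _spr_readouts(panel, config)
    fits = _dose_fits(panel)

    ctrl_eq = readouts[control]["binding_eq_RU"]
    ctrl_decay = readouts[control]["fh_decay_RU"]
    ctrl_ca = fits[control]["cofactor"]
    ctrl_ap = fits[control]["ap_immuno"]
    ctrl_yield = panel.yields[control]
    if ctrl_yield <= 0:
        raise DegenerateControlError("control yield must be > 0")

    # control/variant AP EC50s by interpolation at 50% inhibition, against the
    # control-defined span when shared-plateau mode is on
    def ap_ec50(fit: FourPLFit) -> float:
        ref = ctrl_ap if config.ap_shared_plateau else None
        return ec50_by_interpolation(fit, 50.0, reference=ref)

    ratio_sets = []
    for name in panel.protein_names:
        # a measured ratio below zero (possible for near-zero readouts under
        # noise) has no physical meaning and is floored at 0
        binding_vc = max(0.0, _binding_ratio(readouts[name]["binding_eq_RU"], ctrl_eq))
        daa_vc = max(0.0, _daa_ratio(readouts[name]["fh_decay_RU"], ctrl_decay))
        try:
            ca_cv = ec50_ratio(ctrl_ca, fits[name]["cofactor"])
        except UnreliableFitError:
            ca_cv = None
        try:
            ap_cv = ap_ec50(ctrl_ap) / ap_ec50(fits[name]["ap_immuno"])
            if not (fits[name]["ap_immuno"].reliable and ctrl_ap.reliable):
                ap_cv = None
        except (UnreliableFitError, NoCrossingError):
            ap_cv = None
        hemo = hemolysis_ternary_score(
            panel.curves[name]["hemolysis"], panel.curves[control]["hemolysis"],
            config.hemolysis_rule,
        )
        ratio_sets.append(AssayRatioSet(
            variant_name=name,
            binding_vc=binding_vc,
            daa_vc=daa_vc,
            ca_cv=ca_cv,
            ap_cv=ap_cv,
            yield_vc=panel.yields[name] / ctrl_yield,
            hemolysis_score=hemo.score,
        ))

    results = score_panel(
        ratio_sets,
        defective_below=config.ces_defective_below,
        minimal_above=config.ces_minimal_above,
        partial=config.partial_ces,
    )

    # band calls on the four assay ratios (yield and hemolysis have no band)
    band_rows = []
    for r in ratio_sets:
        for comp, assay in _BAND_ASSAY_BY_COMPONENT.items():
            v = getattr(r, comp)
            if v is None:
                continue
            call = classify_assay_ratio(assay, v, {k: tuple(b) for k, b in config.bands.items()})
            band_rows.append({"variant_name": r.variant_name, "assay": assay,
                              "ratio": v, "call": call.call})
    band_calls = pd.DataFrame(band_rows)

    variant_sets = [r for r in ratio_sets if r.variant_name != control]
    if len(variant_sets) >= 3:
        correlations = assay_correlations(variant_sets, method=config.correlation_method)
    else:
        # too few variants for a meaningful correlation structure
        from .scoring import CONTINUOUS_COMPONENTS
        correlations = pd.DataFrame(np.nan, index=list(CONTINUOUS_COMPONENTS),
                                    columns=list(CONTINUOUS_COMPONENTS))
    shift = sensitivity_rank_shift(results)

    by_name = {r.variant_name: r for r in results}
    results_table = pd.DataFrame([
        {
            "variant_name": r.variant_name,
            "binding_vc": r.binding_vc, "ca_cv": r.ca_cv, "daa_vc": r.daa_vc,
            "ap_cv": r.ap_cv, "yield_vc": r.yield_vc,
            "hemolysis_score": r.hemolysis_score,
            "ces": by_name[r.variant_name].ces,
            "ces_no_yield": by_name[r.variant_name].ces_no_yield,
            "category": by_name[r.variant_name].category,
            "rank": by_name[r.variant_name].rank,
            "rank_no_yield": by_name[r.variant_name].rank_no_yield,
        }
        for r in ratio_sets
    ]).sort_values("rank").reset_index(drop=True)

    readout_table = pd.DataFrame([
        {"protein_id": name, "assay": assay, "readout": value}
        for name, d in readouts.items() for assay, value in d.items()
    ])
    fit_table = pd.DataFrame([
        {
            "protein_id": name, "assay": assay, "bottom": f.bottom, "top": f.top,
            "hill": f.hill, "ec50_uM": f.ec50, "direction": f.direction,
            "rss": f.rss, "converged": f.converged, "reliable": f.reliable,
        }
        for name, d in fits.items() for assay, f in d.items()
    ])

    return PanelResults(readout_table, fit_table, ratio_sets, results,
                        results_table, band_calls, correlations, shift)


def run_pipeline(
    config: PipelineConfig, input_dir: str | Path, output_dir: str | Path
) -> PanelResults:
    """File-based pipeline: read a panel directory, analyze, write tables.

    Outputs are deterministic given identical inputs and config (no
    timestamps), so reruns are byte-identical.  A stage failure aborts with a
    stage-named error after writing a partial-output manifest.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    meta = {"config_hash": config_hash(config), "seed": config.seed,
            "fhces_version": __version__}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            manifest = {"failed_stage": name, "error": str(exc), "written": written}
            (output_dir / "partial_manifest.json").write_text(
                json.dumps(manifest, indent=2) + "\n")
            raise PipelineStageError(name, exc) from exc

    panel = stage("read-panel", lambda: read_panel(input_dir))
    res = stage("analyze", lambda: analyze_panel(panel, config))

    def emit(df, fname):
        write_table(df, output_dir / fname, meta)
        written.append(fname)

    stage("write-readouts", lambda: emit(res.readouts, "spr_readouts.tsv"))
    stage("write-fits", lambda: emit(res.fits, "dose_response_fits.tsv"))
    stage("write-results", lambda: emit(res.results_table, "ces_results.tsv"))
    stage("write-bands", lambda: emit(res.band_calls, "band_calls.tsv"))
    stage("write-rank-shift", lambda: emit(res.rank_shift.table, "rank_shift.tsv"))
    stage("write-correlations", lambda: emit(
        res.correlations.reset_index(names="component"), "assay_correlations.tsv"))
    save_config(config, output_dir / "config.yaml")
    log = dict(meta)
    log.update({
        "n_proteins": len(panel.protein_names),
        "control": panel.control_name,
        "n_unreliable_components": int(sum(
            sum(v is None for v in r.components().values()) for r in res.ratio_sets)),
        "stages": ["read-panel", "analyze"] + written,
    })
    (output_dir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return res


def render_report(
    results: PanelResults,
    output_dir: str | Path,
    registry: list[VariantRecord] | None = None,
) -> Path:
    """Write ``report.txt`` and ``ces_plot.png`` (ascending-CES bar summary).

    With a registry, known AMD odds ratios are overlaid on a second axis;
    variants without a known odds ratio simply have no overlay point.
    Without a registry the report is rendered with a logged warning line.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not results.results:
        raise NoDataError("results bundle is empty")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    ranked = results.results  # already ascending by CES

    odds = {}
    if registry is not None:
        odds = {r.variant_name: r.odds_ratio for r in registry if r.odds_ratio is not None}

    lines = ["Combined Efficacy Score summary", "=" * 31, ""]
    if registry is None:
        lines.append("WARNING: no variant registry supplied; odds-ratio overlay omitted")
        lines.append("")
    lines.append(f"{'rank':>4}  {'variant':<12} {'CES':>7}  {'CES(no yield)':>13}  "
                 f"{'category':<14} {'odds ratio':>10}")
    for r in ranked:
        orr = odds.get(r.variant_name)
        lines.append(
            f"{r.rank:>4}  {r.variant_name:<12} {r.ces:>7.2f}  {r.ces_no_yield:>13.2f}  "
            f"{r.category:<14} {orr if orr is not None else '—':>10}"
        )
    lines.append("")
    counts = {}
    for r in ranked:
        counts[r.category] = counts.get(r.category, 0) + 1
    lines.append("Group sizes: " + ", ".join(f"{k}={v}" for k, v in sorted(counts.items())))
    shift = results.rank_shift
    lines.append("")
    lines.append(f"Yield-omission sensitivity (bottom-{shift.k} membership):")
    lines.append(f"  left bottom-{shift.k}:    {sorted(shift.left_bottom) or '(none)'}")
    lines.append(f"  entered bottom-{shift.k}: {sorted(shift.entered_bottom) or '(none)'}")
    report_path = output_dir / "report.txt"
    report_path.write_text("\n".join(lines) + "\n")

    names = [r.variant_name for r in ranked]
    ces = [r.ces for r in ranked]
    colors = {"defective": "#c23b3b", "marginal": "#e0a13c", "minimal_impact": "#3b7fc2"}
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(names)), 4.5))
    ax.bar(names, ces, color=[colors[r.category] for r in ranked])
    ax.axhline(75, ls="--", lw=0.8, color="0.4")
    ax.axhline(84, ls="--", lw=0.8, color="0.4")
    ax.set_ylabel("CES (control = 100)")
    ax.tick_params(axis="x", rotation=90)
    if odds:
        ax2 = ax.twinx()
        xs = [i for i, n in enumerate(names) if n in odds]
        ax2.plot(xs, [odds[names[i]] for i in xs], "ko", ms=4)
        ax2.set_ylabel("AMD odds ratio")
    fig.tight_layout()
    fig.savefig(output_dir / "ces_plot.png", dpi=120)
    plt.close(fig)
    return report_path
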