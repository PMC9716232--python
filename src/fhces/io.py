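"""Plain-text file formats for traces, curves, truths, yields and panels.

Everything is tab-separated text with explicit headers.  Sensorgram and
dose–response files carry a small ``# key: value`` header block (protein id,
assay, phase marks / direction hints) ahead of the column header.  Floats are
written with ``repr`` so a write→read round trip reproduces values exactly.

Panel directory layout (produced by :func:`write_panel`):

    panel_dir/
      truth.tsv
      yields.tsv
      sensorgrams/<protein>_binding.tsv
      sensorgrams/<protein>_decay.tsv
      sensorgrams/intrinsic_decay.tsv
      dose_response/<protein>_<assay>.tsv
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .doseresponse import DoseResponseCurve
from .errors import ParseError
from .simulate import Panel, PanelDesign, SyntheticTruth
from .spr import Sensorgram

__all__ = [
    "write_sensorgram", "read_sensorgram",
    "write_dose_response", "read_dose_response",
    "write_truths", "read_truths",
    "write_yields", "read_yields",
    "write_panel", "read_panel",
    "write_table",
]

_F = repr  # full-precision float formatting


def _write_header(fh, meta: dict) -> None:
    for k, v in meta.items():
        fh.write(f"# {k}: {v}\n")


def _read_header(path: Path) -> tuple[dict, int]:
    meta, n = {}, 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    return meta, n


# -- sensorgrams -------------------------------------------------------------

def write_sensorgram(s: Sensorgram, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        meta = {"protein_id": s.protein_id, "assay": s.assay}
        for k, v in s.phase_marks.items():
            meta[f"mark_{k}"] = _F(float(v))
        _write_header(fh, meta)
        fh.write("time_s\tresponse_RU\n")
        for t, r in zip(s.times, s.responses):
            fh.write(f"{_F(float(t))}\t{_F(float(r))}\n")


def read_sensorgram(path: str | Path) -> Sensorgram:
    path = Path(path)
    meta, skip = _read_header(path)
    try:
        df = pd.read_csv(path, sep="\t", skiprows=skip, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"cannot parse sensorgram {path}: {exc}") from exc
    if not {"time_s", "response_RU"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns time_s, response_RU")
    marks = {k[len("mark_"):]: float(v) for k, v in meta.items() if k.startswith("mark_")}
    return Sensorgram(
        df["time_s"].to_numpy(float), df["response_RU"].to_numpy(float),
        marks, protein_id=meta.get("protein_id", ""), assay=meta.get("assay", "binding"),
    )


# -- dose–response curves ----------------------------------------------------

def write_dose_response(curve: DoseResponseCurve, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(fh, {"protein_id": curve.protein_id, "assay": curve.assay})
        reps = [f"rep{i + 1}" for i in range(curve.n_reps)]
        fh.write("conc_uM\t" + "\t".join(reps) + "\n")
        for c, row in zip(curve.concentrations, curve.responses):
            fh.write(_F(float(c)) + "\t" + "\t".join(_F(float(v)) for v in row) + "\n")


def read_dose_response(path: str | Path) -> DoseResponseCurve:
    path = Path(path)
    meta, skip = _read_header(path)
    try:
        df = pd.read_csv(path, sep="\t", skiprows=skip, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"cannot parse dose-response table {path}: {exc}") from exc
    if "conc_uM" not in df.columns or df.shape[1] < 2:
        raise ParseError(f"{path}: expected conc_uM plus replicate columns")
    reps = [c for c in df.columns if c != "conc_uM"]
    return DoseResponseCurve(
        df["conc_uM"].to_numpy(float), df[reps].to_numpy(float),
        assay=meta.get("assay", "cofactor"), protein_id=meta.get("protein_id", ""),
    )


# -- truth and yield tables --------------------------------------------------

TRUTH_COLUMNS = ["variant_name", "binding_mult", "daa_mult", "ca_ec50_mult",
                 "ap_ec50_mult", "hemolysis_class", "yield_mult"]


def write_truths(truths: Iterable[SyntheticTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truths:
            fh.write("\t".join([
                t.variant_name, _F(t.binding_mult), _F(t.daa_mult),
                _F(t.ca_ec50_mult), _F(t.ap_ec50_mult),
                t.hemolysis_class, _F(t.yield_mult),
            ]) + "\n")


def read_truths(path: str | Path) -> list[SyntheticTruth]:
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"cannot parse truth table {path}: {exc}") from exc
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: truth table lacks columns {sorted(missing)}")
    return [
        SyntheticTruth(
            variant_name=str(row.variant_name),
            binding_mult=float(row.binding_mult),
            daa_mult=float(row.daa_mult),
            ca_ec50_mult=float(row.ca_ec50_mult),
            ap_ec50_mult=float(row.ap_ec50_mult),
            hemolysis_class=str(row.hemolysis_class),
            yield_mult=float(row.yield_mult),
        )
        for row in df.itertuples(index=False)
    ]


def write_yields(yields: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tyield_mg_per_L\n")
        for name, y in yields.items():
            fh.write(f"{name}\t{_F(float(y))}\n")


def read_yields(path: str | Path) -> dict[str, float]:
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"cannot parse yields table {path}: {exc}") from exc
    if not {"protein_id", "yield_mg_per_L"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns protein_id, yield_mg_per_L")
    return {str(r.protein_id): float(r.yield_mg_per_L) for r in df.itertuples(index=False)}


# -- whole panels ------------------------------------------------------------

def write_panel(panel: Panel, panel_dir: str | Path) -> None:
    """Write a synthetic panel (truth table alongside, for recovery testing)."""
    panel_dir = Path(panel_dir)
    sens = panel_dir / "sensorgrams"
    dose = panel_dir / "dose_response"
    sens.mkdir(parents=True, exist_ok=True)
    dose.mkdir(parents=True, exist_ok=True)
    write_truths(panel.truths, panel_dir / "truth.tsv")
    write_yields(panel.yields, panel_dir / "yields.tsv")
    write_sensorgram(panel.decay_intrinsic, sens / "intrinsic_decay.tsv")
    for name in panel.protein_names:
        write_sensorgram(panel.binding[name], sens / f"{name}_binding.tsv")
        write_sensorgram(panel.decay_fh[name], sens / f"{name}_decay.tsv")
        for assay, curve in panel.curves[name].items():
            write_dose_response(curve, dose / f"{name}_{assay}.tsv")


def read_panel(panel_dir: str | Path, design: PanelDesign | None = None) -> Panel:
    """Read a panel directory back into memory (inverse of :func:`write_panel`)."""
    panel_dir = Path(panel_dir)
    truths = read_truths(panel_dir / "truth.tsv")
    yields = read_yields(panel_dir / "yields.tsv")
    sens = panel_dir / "sensorgrams"
    dose = panel_dir / "dose_response"
    binding, decay_fh, curves = {}, {}, {}
    for t in truths:
        name = t.variant_name
        binding[name] = read_sensorgram(sens / f"{name}_binding.tsv")
        decay_fh[name] = read_sensorgram(sens / f"{name}_decay.tsv")
        curves[name] = {}
        for assay in ("cofactor", "ap_immuno", "hemolysis"):
            p = dose / f"{name}_{assay}.tsv"
            if p.exists():
                curves[name][assay] = read_dose_response(p)
    intrinsic = read_sensorgram(sens / "intrinsic_decay.tsv")
    return Panel(truths, design or PanelDesign(), 0, binding, decay_fh,
                 intrinsic, curves, yields)


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a results DataFrame as TSV with an optional provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        if meta:
            _write_header(fh, meta)
        # default float formatting is shortest-round-trip, so reads are exact
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
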