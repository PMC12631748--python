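"""Curve I/O, analysis configuration, pipeline and report tables.

Curves travel as 2- or 3-column ASCII (q, I[, σ]) with ``#`` comments,
whitespace- or comma-delimited.  The pipeline runs the full analysis on a
set of samples — lineshape fit, Bragg spacing, swelling law, Caillé
parameter, compression modulus — and renders a report table mirroring the
standard presentation of lamellar SANS results, with not-determined
uncertainties printed as ``N.D.``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    MembraneGeometry,
    NalletParameters,
    SampleComposition,
    ScatteringCurve,
    _require,
)
from .fitting import (
    NalletFitter,
    SwellingLawFit,
    detect_bragg_peak,
    estimate_thickness_kratky,
)
from .models import (
    DEFAULT_TEMPERATURE,
    K_B,
    bragg_spacing,
    caille_helfrich,
    helfrich_compression_modulus,
)

__all__ = [
    "read_curve",
    "write_curve",
    "SampleSpec",
    "AnalysisConfig",
    "ReportTable",
    "run_pipeline",
]

logger = logging.getLogger("lamsans")

#: Sentinel rendered for a not-determined uncertainty.
ND = "N.D."


# ---------------------------------------------------------------------------
# curve I/O
# ---------------------------------------------------------------------------

def read_curve(path: Union[str, Path], q_unit: str = "1/A",
               label: Optional[str] = None) -> ScatteringCurve:
    """Read a reduced I(q) curve from 2- or 3-column ASCII.

    Comment lines start with ``#``; columns may be separated by
    whitespace or commas.  ``q_unit`` is ``"1/A"`` (default) or
    ``"1/nm"`` (converted to Å⁻¹).  Rows are sorted by q if needed (with
    a logged notice); negative intensities are clipped to zero with a
    logged warning.
    """
    path = Path(path)
    rows: List[List[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.replace(",", " ").split()
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric data: {text!r}") from exc
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    ncol = len(rows[0])
    if ncol not in (2, 3) or any(len(r) != ncol for r in rows):
        raise ValueError(f"{path}: expected 2 or 3 numeric columns on every row")
    arr = np.asarray(rows, dtype=float)

    q = arr[:, 0]
    if q_unit in ("1/nm", "nm^-1", "nm-1"):
        q = q / 10.0
    elif q_unit not in ("1/A", "A^-1", "A-1"):
        raise ValueError(f"unknown q_unit {q_unit!r}")

    order = np.argsort(q, kind="stable")
    if not np.array_equal(order, np.arange(q.size)):
        logger.info("%s: q rows were not sorted; sorting", path)
        arr = arr[order]
        q = q[order]
    if np.any(np.diff(q) == 0.0):
        raise ValueError(f"{path}: duplicate q values")

    intensity = arr[:, 1]
    if np.any(intensity < 0.0):
        logger.warning("%s: %d negative intensities clipped to zero",
                       path, int(np.sum(intensity < 0.0)))
        intensity = np.maximum(intensity, 0.0)
    sigma = arr[:, 2] if ncol == 3 else None
    return ScatteringCurve(q, intensity, sigma,
                           label=label if label is not None else path.stem)


def write_curve(curve: ScatteringCurve, path: Union[str, Path]) -> None:
    """Write a curve as 3-column (or 2-column) ASCII, 9 significant digits."""
    path = Path(path)
    cols = [curve.q, curve.intensity]
    header = "q(1/A) I(1/cm)"
    if curve.sigma is not None:
        cols.append(curve.sigma)
        header += " sigma(1/cm)"
    if curve.label:
        header = f"{curve.label}\n{header}"
    np.savetxt(path, np.column_stack(cols), fmt="%.9g", header=header)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SampleSpec:
    """One sample of an analysis run: either a path to an ASCII curve or
    an in-memory curve, plus its composition and optional windows."""

    composition: SampleComposition
    path: Optional[Union[str, Path]] = None
    curve: Optional[ScatteringCurve] = None
    q_window: Optional[Tuple[float, float]] = None
    thickness_window: Optional[Tuple[float, float]] = None
    q_unit: str = "1/A"

    def load(self) -> ScatteringCurve:
        if self.curve is not None:
            return self.curve
        _require(self.path is not None, "sample needs either a curve or a path")
        return read_curve(self.path, q_unit=self.q_unit)


@dataclass
class AnalysisConfig:
    """Configuration of a pipeline run; the seed is recorded in all outputs."""

    samples: List[SampleSpec] = field(default_factory=list)
    seed: int = 0
    n_restarts: int = 5
    fit_background: bool = False
    temperature: float = DEFAULT_TEMPERATURE
    kappa: Optional[float] = None       # J; defaults to k_B·T
    output_dir: Optional[Union[str, Path]] = None
    formats: Tuple[str, ...] = ("csv", "json")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).resolve().parent
        samples = []
        for s in raw.get("samples", []):
            comp = SampleComposition(
                phi=float(s["phi"]),
                omega=float(s.get("omega", 1.26)),
                gamma=float(s.get("gamma", 0.0)),
                psi=float(s.get("psi", 0.0)),
                temperature=float(s.get("temperature", raw.get("temperature",
                                                               DEFAULT_TEMPERATURE))),
            )
            p = Path(s["path"])
            if not p.is_absolute():
                p = base / p
            samples.append(SampleSpec(
                composition=comp, path=p,
                q_window=tuple(s["q_window"]) if "q_window" in s else None,
                thickness_window=(tuple(s["thickness_window"])
                                  if "thickness_window" in s else None),
                q_unit=s.get("q_unit", "1/A"),
            ))
        return cls(
            samples=samples,
            seed=int(raw.get("seed", 0)),
            n_restarts=int(raw.get("n_restarts", 5)),
            fit_background=bool(raw.get("fit_background", False)),
            temperature=float(raw.get("temperature", DEFAULT_TEMPERATURE)),
            kappa=raw.get("kappa"),
            output_dir=raw.get("output_dir"),
            formats=tuple(raw.get("formats", ("csv", "json"))),
        )


# ---------------------------------------------------------------------------
# report table
# ---------------------------------------------------------------------------

@dataclass
class ReportTable:
    """Per-sample analysis results plus the series-level swelling fit.

    ``table`` columns: phi, the five lineshape parameters with standard
    errors (NaN = not determined), reduced χ², the Bragg-derived repeat
    distance d (Å), and — when a swelling thickness is available — the
    Caillé parameter η and Helfrich compression modulus B̄ (Pa).
    """

    table: pd.DataFrame
    swelling: Optional["object"] = None      # SwellingFit
    delta: Optional[float] = None            # Å, swelling-law dry thickness
    delta_err: Optional[float] = None
    seed: int = 0

    def to_text(self) -> str:
        df = self.table.copy()
        for col in df.columns:
            if col.endswith("_err"):
                df[col] = [ND if (isinstance(v, float) and not np.isfinite(v)) else f"{v:.4g}"
                           for v in df[col]]
        lines = [df.to_string(index=False)]
        if self.delta is not None:
            err = f" +/- {self.delta_err:.2g}" if self.delta_err is not None else ""
            lines.append(f"swelling-law dry thickness delta = {self.delta:.4g}{err} A")
        lines.append(f"seed = {self.seed}")
        return "\n".join(lines)

    def to_json(self) -> str:
        records = []
        for rec in self.table.to_dict(orient="records"):
            records.append({k: (ND if isinstance(v, float) and not np.isfinite(v) else v)
                            for k, v in rec.items()})
        payload = {"seed": self.seed, "samples": records}
        if self.delta is not None:
            payload["swelling"] = {"delta_A": self.delta, "delta_err_A": self.delta_err}
        return json.dumps(payload, indent=2)

    def write(self, output_dir: Union[str, Path],
              formats: Sequence[str] = ("csv", "json")) -> List[Path]:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        if "csv" in formats:
            p = out / "report.csv"
            self.table.to_csv(p, index=False)
            written.append(p)
        if "json" in formats:
            p = out / "report.json"
            p.write_text(self.to_json())
            written.append(p)
        if "txt" in formats:
            p = out / "report.txt"
            p.write_text(self.to_text() + "\n")
            written.append(p)
        return written


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: AnalysisConfig) -> ReportTable:
    """Run the full analysis over all configured samples.

    Per sample: load → lineshape fit → Bragg-peak detection → repeat
    distance d = 2π/q0.  Series level: through-origin swelling fit of
    (ϕ, d) over the samples with a peak gives the dry thickness δ; each
    sample then gets a Caillé parameter from the Helfrich-limit geometry
    (δ, d) and a compression modulus from the undulation repulsion with
    bending modulus κ (default k_B·T).  Failures are isolated per sample
    and reported as failed rows; the pipeline continues.
    """
    rows: List[dict] = []
    kappa = config.kappa if config.kappa is not None else K_B * config.temperature

    for spec in config.samples:
        phi = spec.composition.phi
        row: dict = {"sample": "", "phi": phi, "status": "ok"}
        try:
            curve = spec.load()
            row["sample"] = curve.label or f"phi={phi:g}"
            fitter = NalletFitter(q_window=spec.q_window,
                                  fit_background=config.fit_background,
                                  n_restarts=config.n_restarts,
                                  random_state=config.seed)
            fitter.fit(curve)
            p, u = fitter.parameters_, fitter.uncertainties_
            row.update(A_z=p.A_z, A_z_err=u[0], xi_p=p.xi_p, xi_p_err=u[1],
                       A_B=p.A_B, A_B_err=u[2], xi_l=p.xi_l, xi_l_err=u[3],
                       q0=p.q0, q0_err=u[4], chi2_reduced=fitter.chi2_reduced_)
            q_peak = detect_bragg_peak(curve)
            if q_peak is not None and p.q0 > 0:
                row["d"] = bragg_spacing(p.q0)
            else:
                row["d"] = np.nan
            if spec.thickness_window is not None:
                est = estimate_thickness_kratky(curve, phi, spec.thickness_window)
                row["delta_kratky"] = est.delta
                row["delta_kratky_err"] = est.delta_err
        except Exception as exc:  # noqa: BLE001 - per-sample isolation
            logger.error("sample phi=%g failed: %s", phi, exc)
            row["status"] = f"failed: {exc}"
        rows.append(row)

    df = pd.DataFrame(rows)
    swelling = None
    delta = delta_err = None
    if "d" in df.columns:
        ok = df["status"].eq("ok") & np.isfinite(df["d"].astype(float))
        if ok.any():
            pts = df.loc[ok, ["phi", "d"]].to_numpy(dtype=float)
            sw = SwellingLawFit(through_origin=True).fit(pts)
            swelling, delta, delta_err = sw.fit_, sw.delta_, sw.delta_err_
            eta, bbar = [], []
            for _, r in df.iterrows():
                d = float(r.get("d", np.nan))
                if r["status"] == "ok" and np.isfinite(d) and d >= delta:
                    geom = MembraneGeometry(delta=delta, d=d)
                    eta.append(caille_helfrich(geom))
                    bbar.append(helfrich_compression_modulus(
                        geom, kappa, config.temperature))
                else:
                    eta.append(np.nan)
                    bbar.append(np.nan)
            df["eta"] = eta
            df["Bbar_Pa"] = bbar

    report = ReportTable(table=df, swelling=swelling, delta=delta,
                         delta_err=delta_err, seed=config.seed)
    if config.output_dir is not None:
        report.write(config.output_dir, config.formats)
    return report
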