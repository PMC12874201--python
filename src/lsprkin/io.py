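"""File formats, reports, and the end-to-end M_n determination pipeline.

Sensorgram CSV dialect: UTF-8, ``# key=value`` comment lines for metadata
(``analyte``, ``monomeric_concentration_mM``, ``injection_start_s``,
``injection_end_s``, ``flow_rate_uL_min``), then a header row
``time_s,ru_active,ru_reference`` (the reference column is optional) and
numeric rows with '.' as the decimal separator.  Writing is canonical
(``%.10g``), so write -> read -> write is byte-stable.

Two entry points run the full analysis:

* :func:`run_pipeline_from_sensorgrams` — preprocess and fit raw traces for
  both orientations, then regress and solve M_n.
* :func:`run_pipeline_from_rate_tables` — start from (concentration, k_obs)
  tables, the level at which published kinetic results are reported.
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import CsvFormatError, DomainError, PipelineError
from .fitting import aggregate_replicates, fit_one_phase, fit_two_phase
from .model import KineticParams, PolymerSpec, Sensorgram
from .molweight import MnResult, estimate_mn, monomeric_to_polymeric
from .preprocess import prepare
from .regression import RateLine, dissociation_constant_nM, fit_rate_line, kinetic_params_from_line

logger = logging.getLogger("lsprkin")

_META_KEYS = {
    "analyte", "analyte_M_o", "analyte_M_n", "monomeric_concentration_mM",
    "injection_start_s", "injection_end_s", "flow_rate_uL_min",
}


def write_sensorgram_csv(s: Sensorgram, path) -> None:
    """Write a sensorgram in the package CSV dialect (canonical formatting)."""
    lines = []
    if s.analyte is not None:
        lines.append(f"# analyte={s.analyte.name}")
        lines.append(f"# analyte_M_o={s.analyte.repeat_unit_mass:.10g}")
        if s.analyte.chain_mass is not None:
            lines.append(f"# analyte_M_n={s.analyte.chain_mass:.10g}")
    if s.monomeric_concentration_mM is not None:
        lines.append(f"# monomeric_concentration_mM={s.monomeric_concentration_mM:.10g}")
    lines.append(f"# injection_start_s={s.injection_start:.10g}")
    lines.append(f"# injection_end_s={s.injection_end:.10g}")
    if s.flow_rate_uL_min is not None:
        lines.append(f"# flow_rate_uL_min={s.flow_rate_uL_min:.10g}")
    cols = "time_s,ru_active" + (",ru_reference" if s.has_reference else "")
    lines.append(cols)
    for i in range(s.time.size):
        row = f"{s.time[i]:.10g},{s.response_active[i]:.10g}"
        if s.has_reference:
            row += f",{s.response_reference[i]:.10g}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_sensorgram_csv(path) -> Sensorgram:
    """Read a sensorgram CSV, reporting malformed content with line numbers."""
    text = Path(path).read_text(encoding="utf-8")
    meta: dict[str, str] = {}
    header_line = None
    data_start = None
    lines = text.splitlines()
    for ln, raw in enumerate(lines, start=1):
        stripped = raw.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if "=" not in body:
                raise CsvFormatError(f"line {ln}: metadata comment without key=value")
            k, v = body.split("=", 1)
            meta[k.strip()] = v.strip()
            continue
        header_line = ln
        break
    if header_line is None:
        raise CsvFormatError("no header row found")
    header = [c.strip() for c in lines[header_line - 1].split(",")]
    if header[:2] != ["time_s", "ru_active"]:
        raise CsvFormatError(
            f"line {header_line}: header must start 'time_s,ru_active', got {header!r}"
        )
    has_ref = len(header) >= 3 and header[2] == "ru_reference"
    data_start = header_line

    body = "\n".join(lines[data_start:])
    try:
        df = pd.read_csv(_io.StringIO(body), header=None, names=header)
    except Exception as e:  # noqa: BLE001 - re-raise as dialect error
        raise CsvFormatError(f"unparseable data rows: {e}") from e
    for col in header:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise CsvFormatError(
                f"line {data_start + int(bad[0]) + 1}: non-numeric value in column {col!r}"
            )
    t = df["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        first_bad = int(np.argmax(np.diff(t) <= 0)) + 1
        raise CsvFormatError(
            f"line {data_start + first_bad + 1}: time not strictly increasing"
        )

    def _meta_float(key):
        if key not in meta:
            return None
        try:
            return float(meta[key])
        except ValueError as e:
            raise CsvFormatError(f"metadata {key}={meta[key]!r} is not numeric") from e

    for required in ("injection_start_s", "injection_end_s"):
        if required not in meta:
            raise CsvFormatError(f"missing required metadata '{required}'")
    analyte = None
    if "analyte" in meta:
        mo = _meta_float("analyte_M_o")
        if mo is None:
            raise CsvFormatError("metadata 'analyte' requires 'analyte_M_o'")
        analyte = PolymerSpec(meta["analyte"], mo, _meta_float("analyte_M_n"))
    return Sensorgram(
        time=t,
        response_active=df["ru_active"].to_numpy(float),
        response_reference=df["ru_reference"].to_numpy(float) if has_ref else None,
        injection_start=_meta_float("injection_start_s"),
        injection_end=_meta_float("injection_end_s"),
        analyte=analyte,
        monomeric_concentration_mM=_meta_float("monomeric_concentration_mM"),
        flow_rate_uL_min=_meta_float("flow_rate_uL_min"),
        metadata={k: v for k, v in meta.items() if k not in _META_KEYS},
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Two-orientation M_n determination setup.

    Exactly one of the two polymers (the ``unknown_polymer``) lacks M_n; the
    ``known_polymer`` provides the chain-basis conversion for its own
    gradient.
    """

    known_polymer: PolymerSpec
    unknown_polymer: PolymerSpec
    gradient_mM: Sequence[float] = (1.0, 0.5, 0.25, 0.125, 0.0625)
    replicates: int = 2
    fit_model: str = "one_phase"  # or "two_phase"
    free_offset: bool = False
    use_reference: bool = True
    inverse_variance_weights: bool = False

    def __post_init__(self):
        if self.known_polymer.chain_mass is None:
            raise DomainError("known_polymer must carry M_n (chain_mass)")
        if self.unknown_polymer.chain_mass is not None:
            raise DomainError("unknown_polymer must not carry M_n in an M_n run")
        g = list(self.gradient_mM)
        if len(g) != len(set(g)) or any(c <= 0 for c in g):
            raise DomainError("gradient concentrations must be positive and distinct")
        if self.fit_model not in ("one_phase", "two_phase"):
            raise DomainError("fit_model must be 'one_phase' or 'two_phase'")


@dataclass
class PipelineResult:
    """Everything the two-orientation analysis produces."""

    known_line: RateLine
    unknown_line: RateLine
    params: KineticParams
    kd_nM: float
    mn: MnResult
    kobs_known: dict = field(default_factory=dict)  # conc_mM -> ReplicateSummary
    kobs_unknown: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _kobs_table_from_sensorgrams(sensorgrams, cfg: ExperimentConfig, stage: str):
    """Fit every trace, aggregate replicates; returns {conc_mM: ReplicateSummary}."""
    by_conc: dict[float, list[float]] = {}
    for s in sensorgrams:
        if s.monomeric_concentration_mM is None:
            raise PipelineError(stage, "sensorgram lacks monomeric_concentration_mM")
        try:
            tr = prepare(s, use_reference=cfg.use_reference)
            fit = (fit_two_phase(tr) if cfg.fit_model == "two_phase"
                   else fit_one_phase(tr, free_offset=cfg.free_offset))
        except Exception as e:
            raise PipelineError(stage, f"{type(e).__name__}: {e}") from e
        k = fit.k_obs if fit.model == "one_phase" else fit.k_fast
        logger.info("%s: conc=%g mM fitted k_obs=%.5g 1/s (R²=%.4f, %d evals)",
                    stage, s.monomeric_concentration_mM, k, fit.r_squared, fit.n_iter)
        by_conc.setdefault(s.monomeric_concentration_mM, []).append(k)
    return {c: aggregate_replicates(v) for c, v in sorted(by_conc.items(), reverse=True)}


def _lines_from_tables(known, unknown, cfg_known_polymer, weights_known=None,
                       weights_unknown=None, known_basis="monomeric_mM"):
    """(conc, k_obs) tables -> (polymeric-basis line, monomeric-basis line)."""
    if known_basis == "monomeric_mM":
        kc = [monomeric_to_polymeric(c, cfg_known_polymer) for c, _ in known]
    elif known_basis == "polymeric_uM":
        kc = [c for c, _ in known]  # chain concentrations supplied directly
    else:
        raise DomainError(f"unknown basis {known_basis!r}")
    known_line = fit_rate_line(kc, [k for _, k in known], weights=weights_known,
                               basis="polymeric_uM")
    unknown_line = fit_rate_line([c for c, _ in unknown], [k for _, k in unknown],
                                 weights=weights_unknown, basis="monomeric_mM")
    return known_line, unknown_line


def run_pipeline_from_rate_tables(
    known_table: Sequence[tuple[float, float]],
    unknown_table: Sequence[tuple[float, float]],
    known_polymer: PolymerSpec,
    unknown_polymer: PolymerSpec,
    weights_known: Optional[Sequence[float]] = None,
    weights_unknown: Optional[Sequence[float]] = None,
    known_basis: str = "monomeric_mM",
    provenance: Optional[dict] = None,
) -> PipelineResult:
    """M_n determination from (concentration, k_obs 1/s) tables.

    This is the analysis at the level published kinetic results live: the
    known polymer's concentrations are converted to the chain basis (or
    supplied on it directly with ``known_basis="polymeric_uM"``) and
    regressed for k_on/k_off; the unknown polymer's monomeric-basis (mM)
    slope alpha then gives DP = k_on/alpha and M_n = DP*M_o.
    """
    if known_polymer.chain_mass is None and known_basis == "monomeric_mM":
        raise PipelineError("regress", "known polymer lacks M_n")
    known_line, unknown_line = _lines_from_tables(
        known_table, unknown_table, known_polymer, weights_known, weights_unknown,
        known_basis=known_basis,
    )
    params = kinetic_params_from_line(known_line)
    mn = estimate_mn(known_line, unknown_line, unknown_polymer,
                     provenance=provenance or {})
    return PipelineResult(
        known_line=known_line,
        unknown_line=unknown_line,
        params=params,
        kd_nM=dissociation_constant_nM(params),
        mn=mn,
        provenance=provenance or {},
    )


def run_pipeline_from_sensorgrams(
    cfg: ExperimentConfig,
    known_sensorgrams: Sequence[Sensorgram],
    unknown_sensorgrams: Sequence[Sensorgram],
    provenance: Optional[dict] = None,
) -> PipelineResult:
    """Full pipeline from raw traces of both orientations.

    preprocess -> fit transients -> aggregate replicates -> regress both
    orientations -> solve DP and M_n.  Stage failures carry the stage name.
    """
    if not known_sensorgrams:
        raise PipelineError("input", "no sensorgrams for the known-polymer orientation")
    if not unknown_sensorgrams:
        raise PipelineError("input", "no sensorgrams for the unknown-polymer orientation")
    kobs_known = _kobs_table_from_sensorgrams(known_sensorgrams, cfg, "fit-known")
    kobs_unknown = _kobs_table_from_sensorgrams(unknown_sensorgrams, cfg, "fit-unknown")

    def _weights(table):
        if not cfg.inverse_variance_weights:
            return None
        sems = [s.sem_k_obs for s in table.values()]
        if any(v is None or v == 0 for v in sems):
            raise PipelineError("regress", "inverse-variance weights need SEMs (n >= 2)")
        return [1.0 / v**2 for v in sems]

    try:
        result = run_pipeline_from_rate_tables(
            [(c, s.mean_k_obs) for c, s in kobs_known.items()],
            [(c, s.mean_k_obs) for c, s in kobs_unknown.items()],
            cfg.known_polymer,
            cfg.unknown_polymer,
            weights_known=_weights(kobs_known),
            weights_unknown=_weights(kobs_unknown),
            provenance=provenance,
        )
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("regress", f"{type(e).__name__}: {e}") from e
    result.kobs_known = kobs_known
    result.kobs_unknown = kobs_unknown
    return result


def _line_dict(line: RateLine) -> dict:
    return {
        "slope": line.slope, "intercept": line.intercept,
        "se_slope": line.se_slope, "se_intercept": line.se_intercept,
        "r_squared": line.r_squared, "basis": line.basis, "n_points": line.n_points,
    }


def result_to_dict(result: PipelineResult) -> dict:
    """JSON-serializable report of a pipeline run (values, SEs, units, provenance)."""
    return {
        "known_line": _line_dict(result.known_line),
        "unknown_line": _line_dict(result.unknown_line),
        "kinetics": {
            "k_on_per_uM_per_s": result.params.k_on,
            "se_k_on": result.params.se_k_on,
            "k_off_per_s": result.params.k_off,
            "se_k_off": result.params.se_k_off,
            "K_D_nM": result.kd_nM,
        },
        "molecular_weight": {
            "dp": result.mn.dp,
            "dp_reported": result.mn.dp_reported,
            "mn_g_per_mol": result.mn.mn,
            "mn_reported_g_per_mol": result.mn.mn_reported,
            "se_dp": result.mn.se_dp,
            "se_mn": result.mn.se_mn,
            "alpha_per_uM_per_s": result.mn.alpha_used,
            "repeat_unit_mass_g_per_mol": result.mn.repeat_unit_mass,
        },
        "kobs_tables": {
            orientation: {
                str(c): {"mean_k_obs": s.mean_k_obs, "sem_k_obs": s.sem_k_obs, "n": s.n}
                for c, s in table.items()
            }
            for orientation, table in (("known", result.kobs_known),
                                       ("unknown", result.kobs_unknown))
        },
        "provenance": result.provenance,
    }


def write_report(result: PipelineResult, path) -> None:
    """Write the JSON report plus a human-readable text summary alongside it."""
    if result is None:
        raise DomainError("empty result set")
    path = Path(path)
    d = result_to_dict(result)
    path.write_text(json.dumps(d, indent=2) + "\n", encoding="utf-8")
    k = d["kinetics"]
    m = d["molecular_weight"]
    summary = "\n".join([
        "Binding kinetics and molecular-weight determination",
        "---------------------------------------------------",
        f"k_on  = {k['k_on_per_uM_per_s']:.5g} ± {k['se_k_on']:.3g} 1/(uM*s)",
        f"k_off = {k['k_off_per_s']:.5g} ± {k['se_k_off']:.3g} 1/s",
        f"K_D   = {k['K_D_nM']:.0f} nM",
        f"alpha = {m['alpha_per_uM_per_s']:.5g} 1/(uM*s) (monomeric basis)",
        f"DP    = {m['dp']:.1f} (reported {m['dp_reported']})",
        f"M_n   = {m['mn_g_per_mol']:.0f} g/mol (reported {m['mn_reported_g_per_mol']:.0f})",
        f"provenance: {json.dumps(d['provenance'])}",
    ])
    path.with_suffix(".txt").write_text(summary + "\n", encoding="utf-8")
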