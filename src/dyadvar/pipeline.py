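"""End-to-end orchestration of the four-model study design.

The emulated study fits one pooled lag-1 VAR per group x encoding cell
(boys/girls x duration-seconds/occurrence-counts: four models), runs
residual diagnostics, sweeps the conservative last-position orderings
with bootstrap bands, and collapses each model's impulse-response set
into a sign table. This module wires those stages together from either
a coded event log on disk or a synthetic generator configuration, and
writes a fully checksummed artifact directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError, ConvergenceError, DyadvarError
from .irf import (
    DEFAULT_HORIZON,
    DEFAULT_LEVEL,
    DEFAULT_REPS,
    SIGN_WINDOW,
    ConservativeIRFSet,
    SignTable,
    build_sign_table,
    conservative_irf_sweep,
    render_bracket_table,
)
from .panel import MonthlyPanel, aggregate_monthly, read_event_log
from .simulate import GeneratorConfig, generate_events
from .var import DiagnosticsReport, VARModel, diagnose, fit_var, select_lag
from .vocabulary import ENCODINGS, GROUPS, INFANT_CODES, MATERNAL_CODES


@dataclasses.dataclass
class StudyConfig:
    """Configuration of a full group x encoding study run."""

    events_path: str | None = None
    generator: GeneratorConfig | None = None
    groups: Sequence[str] = GROUPS
    encodings: Sequence[str] = ENCODINGS
    lag: int | str = 1                  # fixed order, or "auto" for selection
    p_max: int = 4
    alpha: float = 0.05
    horizon: int = DEFAULT_HORIZON
    reps: int = DEFAULT_REPS
    level: float = DEFAULT_LEVEL
    window: tuple[int, int] = SIGN_WINDOW
    monthly_stat: str = "sum"
    seed: int = 0

    def __post_init__(self):
        if (self.events_path is None) == (self.generator is None):
            raise ConfigurationError(
                "exactly one input source (events_path or generator) must be set"
            )
        bad = set(self.encodings) - set(ENCODINGS)
        if bad:
            raise ConfigurationError(f"unknown encoding(s) {sorted(bad)}")
        if not self.groups or not self.encodings:
            raise ConfigurationError("at least one group and one encoding are required")
        self.window = tuple(self.window)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "generator" in raw and raw["generator"] is not None:
            gen = raw.pop("generator")
            for key in ("coupling_by_group", "intercept_by_group"):
                if key in gen and gen[key] is not None:
                    gen[key] = {g: np.asarray(v, float) for g, v in gen[key].items()}
            if gen.get("innovation_cov") is not None:
                gen["innovation_cov"] = np.asarray(gen["innovation_cov"], float)
            raw["generator"] = GeneratorConfig(**gen)
        return cls(**raw)


@dataclasses.dataclass
class ModelResult:
    """One fitted group x encoding cell (or its recorded failure)."""

    group: str
    encoding: str
    p: int | None = None
    model: VARModel | None = None
    diagnostics: DiagnosticsReport | None = None
    lag_audit: list[DiagnosticsReport] | None = None
    irfs: ConservativeIRFSet | None = None
    sign_table: SignTable | None = None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None

    @property
    def key(self) -> str:
        return f"{self.group}_{self.encoding}"


@dataclasses.dataclass
class StudyReport:
    """All model cells plus run metadata and the warnings log."""

    config: StudyConfig
    results: list[ModelResult]
    metadata: dict
    warnings: list[str] = dataclasses.field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.results)

    def result(self, group: str, encoding: str) -> ModelResult:
        for r in self.results:
            if r.group == group and r.encoding == encoding:
                return r
        raise KeyError(f"no model for ({group}, {encoding})")


def _load_panels(config: StudyConfig) -> dict[str, MonthlyPanel]:
    if config.events_path is not None:
        events = read_event_log(config.events_path)
        # model only the codes the log covers (in canonical Table-1 order);
        # codes never observed would enter as constant zero columns
        from .vocabulary import ALL_CODES
        observed = set(events["code"])
        vocab = [c for c in ALL_CODES if c in observed]
    else:
        events = generate_events(config.generator)
        vocab = list(config.generator.variables)
    return {
        enc: aggregate_monthly(events, enc, stat=config.monthly_stat, vocabulary=vocab)
        for enc in config.encodings
    }


def run_study(config: StudyConfig) -> StudyReport:
    """Run aggregate -> lag selection -> fit -> diagnose -> conservative
    IRF sweep -> sign table for every group x encoding cell.

    A cell whose model cannot be estimated or whose lag search does not
    converge is marked failed in the report (with its audit trail where
    available); the remaining cells still run. The whole run is
    deterministic under a fixed seed.
    """
    t0 = time.time()
    panels = _load_panels(config)
    results: list[ModelResult] = []
    warn_log: list[str] = []
    for ei, encoding in enumerate(config.encodings):
        for gi, group in enumerate(config.groups):
            res = ModelResult(group=group, encoding=encoding)
            child_seed = np.random.SeedSequence([config.seed, ei, gi])
            try:
                sub = panels[encoding].subset_group(group)
                if sub.n_dyads < 1:
                    raise ConfigurationError(f"group {group!r} is empty")
                if config.lag == "auto":
                    sel = select_lag(sub, p_max=config.p_max, alpha=config.alpha)
                    res.p, model = sel.p, sel.model
                    res.lag_audit = sel.audit
                    res.diagnostics = sel.audit[-1]
                else:
                    res.p = int(config.lag)
                    model = fit_var(sub, res.p)
                    res.diagnostics = diagnose(model, alpha=config.alpha)
                res.model = model
                res.irfs = conservative_irf_sweep(
                    sub,
                    p=res.p,
                    horizon=config.horizon,
                    reps=config.reps,
                    level=config.level,
                    seed=child_seed,
                )
                res.sign_table = build_sign_table(
                    res.irfs, window=config.window, group=group, encoding=encoding
                )
            except ConvergenceError as exc:
                res.error = str(exc)
                res.lag_audit = exc.audit
                warn_log.append(f"{res.key}: {exc}")
            except DyadvarError as exc:
                res.error = str(exc)
                warn_log.append(f"{res.key}: {exc}")
            results.append(res)
    metadata = {
        "seed": config.seed,
        "dyadvar_version": __version__,
        "numpy_version": np.__version__,
        "elapsed_seconds": round(time.time() - t0, 3),
        "n_models": len(results),
    }
    return StudyReport(config=config, results=results, metadata=metadata, warnings=warn_log)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(report: StudyReport, outdir: str | Path, force: bool = False) -> dict[str, str]:
    """Write model JSONs, IRF curves, sign tables, diagnostics and a
    checksummed manifest; refuses to overwrite an existing non-empty
    directory unless ``force`` is set.

    Returns the manifest mapping relative file names to SHA-256 digests.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (pass force=True to overwrite)")
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for res in report.results:
        key = res.key
        if res.failed:
            path = outdir / f"model_{key}.FAILED.txt"
            path.write_text(res.error + "\n")
            written.append(path)
            continue
        path = outdir / f"model_{key}.json"
        payload = res.model.to_dict()
        payload["diagnostics"] = res.diagnostics.to_dict() if res.diagnostics else None
        if res.lag_audit:
            payload["lag_audit"] = [a.to_dict() for a in res.lag_audit]
        path.write_text(json.dumps(payload, indent=1))
        written.append(path)
        path = outdir / f"irf_{key}.csv"
        res.irfs.to_frame().to_csv(path, index=False, float_format="%.10g")
        written.append(path)
        path = outdir / f"signtable_{key}.csv"
        res.sign_table.cells.to_csv(path)
        written.append(path)

    # combined bracket tables in the published layout, when both
    # encodings succeeded for at least one group
    dur = {r.group: r.sign_table for r in report.results
           if r.encoding == "duration_seconds" and not r.failed}
    occ = {r.group: r.sign_table for r in report.results
           if r.encoding == "occurrence_count" and not r.failed}
    if dur or occ:
        combined = render_bracket_table(dur or occ, occ or dur)
        infant = [v for v in combined.index if v in INFANT_CODES]
        maternal = [v for v in combined.index if v in MATERNAL_CODES]
        if infant and maternal:
            path = outdir / "signtable_infant_responses.csv"
            combined.loc[infant, maternal].to_csv(path)
            written.append(path)
            path = outdir / "signtable_maternal_responses.csv"
            combined.loc[maternal, infant].to_csv(path)
            written.append(path)
        else:
            path = outdir / "signtable_combined.csv"
            combined.to_csv(path)
            written.append(path)

    path = outdir / "diagnostics.txt"
    lines = [f"dyadvar study report (seed={report.config.seed})"]
    for res in report.results:
        lines.append(f"\n[{res.key}] p={res.p} " + ("FAILED: " + res.error if res.failed else ""))
        if res.diagnostics is not None:
            lines.append(json.dumps(res.diagnostics.to_dict(), indent=1))
    for w in report.warnings:
        lines.append(f"warning: {w}")
    path.write_text("\n".join(lines) + "\n")
    written.append(path)

    # run metadata carries wall-clock timings, so it stays outside the
    # checksummed manifest to keep same-seed reruns byte-identical
    (outdir / "metadata.json").write_text(json.dumps(report.metadata, indent=1))

    manifest = {p.name: _sha256(p) for p in written}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
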