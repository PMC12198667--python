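"""End-to-end pipeline: run configuration, per-endpoint fitting, result
tables, sensitivity ranking, logging and report rendering.

A run is described by a YAML configuration::

    seed: 1
    output_dir: out
    credible_level: 0.90
    mcmc: {iterations: 30000, warmup_fraction: 0.5, chains: 1}
    qc: {max_bmd_bmdl_ratio: 20, max_bmdu_bmdl_ratio: 50}
    datasets:
      - path: study1.csv
        study_id: oral10_I
        endpoints:
          - {endpoint_id: serum_progesterone, ces: +0.10}
          - {endpoint_id: uterus_weight, ces: -0.05}

Per-endpoint seeds derive from the master seed by a stable hash of
(study_id, endpoint_id), so adding endpoints does not perturb existing
results.  Endpoint failures are recorded and skipped, never fatal.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bmd import CesSpec, QcCriteria
from .core import BenchmarkDose
from .data import (
    DoseResponseDataset,
    EndpointResultRow,
    format_sig,
    read_dataset,
    write_result_table,
)
from .bmd import rank_endpoints
from .mcmc import McmcSettings

__all__ = [
    "EndpointSpec",
    "RunConfig",
    "RunBundle",
    "load_run_config",
    "endpoint_seed",
    "run_pipeline",
    "render_report",
]


@dataclass(frozen=True)
class EndpointSpec:
    endpoint_id: str
    ces: float  # signed
    path: str = ""
    study_id: str = ""


@dataclass
class RunConfig:
    endpoints: list[EndpointSpec]
    seed: int = 0
    output_dir: str = "bmdkit_out"
    credible_level: float = 0.90
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    max_bmd_bmdl_ratio: float = 20.0
    max_bmdu_bmdl_ratio: float = 50.0

    def __post_init__(self) -> None:
        if not self.endpoints:
            raise ValueError("run configuration lists no endpoints")
        for e in self.endpoints:
            CesSpec.from_signed(e.ces)  # validates sign/magnitude


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    mcmc_raw = raw.get("mcmc", {})
    mcmc = McmcSettings(
        iterations=int(mcmc_raw.get("iterations", 30000)),
        warmup_fraction=float(mcmc_raw.get("warmup_fraction", 0.5)),
        chains=int(mcmc_raw.get("chains", 1)),
        seed=int(raw.get("seed", 0)),
    )
    qc_raw = raw.get("qc", {})
    endpoints = []
    for d in raw.get("datasets", []):
        for e in d.get("endpoints", []):
            endpoints.append(
                EndpointSpec(
                    endpoint_id=str(e["endpoint_id"]),
                    ces=float(e["ces"]),
                    path=str(d.get("path", "")),
                    study_id=str(d.get("study_id", "")),
                )
            )
    return RunConfig(
        endpoints=endpoints,
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "bmdkit_out")),
        credible_level=float(raw.get("credible_level", 0.90)),
        mcmc=mcmc,
        max_bmd_bmdl_ratio=float(qc_raw.get("max_bmd_bmdl_ratio", 20.0)),
        max_bmdu_bmdl_ratio=float(qc_raw.get("max_bmdu_bmdl_ratio", 50.0)),
    )


def endpoint_seed(master_seed: int, study_id: str, endpoint_id: str) -> int:
    """Stable per-endpoint seed below 2^31."""
    h = zlib.crc32(f"{study_id}:{endpoint_id}".encode())
    return (int(master_seed) * 1_000_003 + h) & 0x7FFFFFFF


@dataclass
class RunBundle:
    """Everything a pipeline run produced."""

    rows: list[EndpointResultRow]
    ranking: list[EndpointResultRow]
    failures: dict[str, str]
    log_lines: list[str]
    results: dict[str, object] = field(default_factory=dict)  # keyed study:endpoint

    @property
    def ok(self) -> bool:
        return not self.failures


def run_pipeline(
    config: RunConfig, datasets: dict[tuple[str, str], DoseResponseDataset] | None = None
) -> RunBundle:
    """Fit every configured endpoint and write the result bundle.

    `datasets` may supply in-memory data keyed by (study_id, endpoint_id);
    otherwise each endpoint's file is read from its configured path.
    Writes results.csv, ranking.csv and run.log under `output_dir`.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    log.append(f"master seed: {config.seed}")
    log.append(
        f"mcmc: iterations={config.mcmc.iterations} "
        f"warmup_fraction={config.mcmc.warmup_fraction} chains={config.mcmc.chains}"
    )
    log.append(
        f"qc thresholds: bmd/bmdl<={config.max_bmd_bmdl_ratio} "
        f"bmdu/bmdl<={config.max_bmdu_bmdl_ratio} "
        f"bmdl>=lowest nonzero dose/10"
    )
    log.append(f"credible level: {config.credible_level}")

    rows: list[EndpointResultRow] = []
    failures: dict[str, str] = {}
    results: dict[str, object] = {}
    for spec in config.endpoints:
        key = f"{spec.study_id}:{spec.endpoint_id}"
        try:
            if datasets is not None and (spec.study_id, spec.endpoint_id) in datasets:
                ds = datasets[(spec.study_id, spec.endpoint_id)]
            else:
                ds = read_dataset(spec.path, spec.study_id, spec.endpoint_id)
            qc = QcCriteria(
                max_bmd_bmdl_ratio=config.max_bmd_bmdl_ratio,
                max_bmdu_bmdl_ratio=config.max_bmdu_bmdl_ratio,
                min_bmdl=ds.lowest_nonzero_dose / 10.0,
            )
            bm = BenchmarkDose(
                ds,
                CesSpec.from_signed(spec.ces),
                settings=config.mcmc,
                credible_level=config.credible_level,
                qc_criteria=qc,
            )
            res = bm.fit(seed=endpoint_seed(config.seed, spec.study_id, spec.endpoint_id))
            results[key] = res
            rows.append(res.to_result_row())
            log.append(
                f"{key}: bmdl={format_sig(res.bmdl)} bmd={format_sig(res.bmd)} "
                f"bmdu={format_sig(res.bmdu)} qc={'pass' if res.qc.passed else 'fail'}"
                + (f" reasons={','.join(res.qc.reasons)}" if res.qc.reasons else "")
                + (" direction-inconsistent" if res.estimate.direction_inconsistent else "")
            )
            for ev in res.events:
                log.append(f"{key}:   {ev}")
            weights = " ".join(
                f"{m}={w:.3f}" for m, w in res.weights.posterior.items()
            )
            log.append(f"{key}:   weights: {weights}")
        except Exception as exc:  # endpoint failures are recorded, not fatal
            failures[key] = f"{type(exc).__name__}: {exc}"
            log.append(f"{key}: FAILED {failures[key]}")

    ranking = rank_endpoints(rows)
    if rows:
        write_result_table(rows, out_dir / "results.csv")
        write_result_table(ranking, out_dir / "ranking.csv")
    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    return RunBundle(
        rows=rows, ranking=ranking, failures=failures, log_lines=log, results=results
    )


def render_report(bundle: RunBundle, comparison=None) -> str:
    """Human-readable report: per-study tables marking QC-accepted rows and
    the two most sensitive (lowest-BMDL/BMD) endpoints, the sensitivity
    ranking, and optionally a POD-vs-NOAEL comparison table."""
    lines: list[str] = []
    lines.append("Benchmark-dose model-averaging report")
    lines.append("=" * 72)
    studies: dict[str, list[EndpointResultRow]] = {}
    for r in bundle.rows:
        studies.setdefault(r.study_id, []).append(r)

    for study, rows in studies.items():
        lines.append("")
        lines.append(f"Study: {study}")
        accepted = [r for r in rows if r.qc_pass]
        low_bmdl = {
            id(r) for r in sorted(accepted, key=lambda r: r.bmdl)[:2]
        }
        low_bmd = {id(r) for r in sorted(accepted, key=lambda r: r.bmd)[:2]}
        header = (
            f"  {'endpoint':<28}{'CES':>6}{'BMDL':>9}{'BMD':>9}{'BMDU':>9}"
            f"{'B/L':>6}{'U/L':>6}  flags"
        )
        lines.append(header)
        for r in rows:
            flags = []
            if r.qc_pass:
                flags.append("accepted")
            if id(r) in low_bmdl:
                flags.append("lowest-BMDL")
            if id(r) in low_bmd:
                flags.append("lowest-BMD")
            rb = f"{r.ratio_bmd_bmdl:.1f}" if r.ratio_bmd_bmdl == r.ratio_bmd_bmdl else "NA"
            ru = (
                f"{r.ratio_bmdu_bmdl:.1f}" if r.ratio_bmdu_bmdl == r.ratio_bmdu_bmdl else "NA"
            )
            lines.append(
                f"  {r.endpoint_id:<28}{r.ces_signed:>+6.2f}"
                f"{format_sig(r.bmdl):>9}{format_sig(r.bmd):>9}{format_sig(r.bmdu):>9}"
                f"{rb:>6}{ru:>6}  {','.join(flags)}"
            )
        if not accepted:
            lines.append("  (no endpoint passed the quality-control criteria)")

    lines.append("")
    lines.append("Sensitivity ranking (QC-accepted first, ascending BMDL):")
    for i, r in enumerate(bundle.ranking, 1):
        tag = "" if r.qc_pass else "  [QC-failed]"
        lines.append(
            f"  {i:>2}. {r.study_id}/{r.endpoint_id}: BMDL {format_sig(r.bmdl)}{tag}"
        )

    if bundle.failures:
        lines.append("")
        lines.append("Failed endpoints:")
        for k, v in bundle.failures.items():
            lines.append(f"  {k}: {v}")

    if comparison is not None:
        lines.append("")
        lines.append("POD vs regulatory effect levels:")
        lines.append(comparison.to_string(index=False))

    return "\n".join(lines) + "\n"
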