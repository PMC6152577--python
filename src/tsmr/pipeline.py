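"""End-to-end two-sample MR analysis: selection → proxies → harmonization → estimation.

`run_analysis` reproduces the standard summary-statistic MR flow on an
exposure/outcome table pair: instruments are selected by p-value threshold
in the exposure GWAS, instruments missing from the outcome GWAS are
replaced by LD proxies (r² >= 0.9 by default), effects are harmonized to
the exposure's effect alleles, and the IVW, weighted-median and MR-Egger
estimators are applied with Cochran's Q / I² heterogeneity.  Binary
outcomes are analyzed on the log-odds scale and additionally reported as
odds ratios.  All randomness (the weighted-median bootstrap) flows through
a single mandatory seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from . import __version__
from .errors import EmptyInstrumentError, ValidationError
from .estimators import (
    LINEAR,
    LOG_ODDS,
    MIN_EGGER_INSTRUMENTS,
    HeterogeneityStats,
    MREstimate,
    egger_estimate,
    ivw_estimate,
    to_odds_ratio,
    weighted_median_estimate,
)
from .harmonize import (
    HarmonizationPolicy,
    HarmonizedInstrument,
    harmonization_report,
    harmonize_datasets,
    orient_for_egger,
)
from .summary_io import (
    ProxyEntry,
    SummaryDataset,
    read_proxy_table,
    read_summary_table,
    select_instruments,
    substitute_proxies,
)

_METHOD_ORDER = ("ivw", "weighted_median", "egger_slope", "egger_intercept")


@dataclass(frozen=True)
class AnalysisConfig:
    """Declarative description of one MR run."""

    exposure_path: str
    outcome_path: str
    proxy_path: str | None = None
    p_threshold: float = 5e-8
    r2_min: float = 0.9
    outcome_type: str = "binary"
    n_boot: int = 1000
    seed: int = 0
    palindromic_eaf_window: float = 0.08
    drop_ambiguous: bool = True
    output_dir: str | None = None

    def policy(self) -> HarmonizationPolicy:
        return HarmonizationPolicy(
            palindromic_eaf_window=self.palindromic_eaf_window,
            drop_ambiguous=self.drop_ambiguous,
        )


@dataclass
class ResultsTable:
    """Per-method estimates plus heterogeneity and instrument accounting."""

    rows: list[MREstimate]
    heterogeneity: HeterogeneityStats
    accounting: dict[str, int]
    outcome_type: str
    or_rows: list[MREstimate] = field(default_factory=list)
    notice: str | None = None
    seed: int | None = None

    def row(self, method: str) -> MREstimate:
        for r in self.rows:
            if r.method == method:
                return r
        raise KeyError(method)

    def to_dict(self) -> dict:
        return {
            "rows": [r.to_dict() for r in self.rows],
            "or_rows": [r.to_dict() for r in self.or_rows],
            "heterogeneity": {
                "Q": self.heterogeneity.Q,
                "df": self.heterogeneity.df,
                "i2": self.heterogeneity.i2,
            },
            "accounting": dict(self.accounting),
            "outcome_type": self.outcome_type,
            "notice": self.notice,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResultsTable":
        return cls(
            rows=[MREstimate(**r) for r in d["rows"]],
            or_rows=[MREstimate(**r) for r in d.get("or_rows", [])],
            heterogeneity=HeterogeneityStats(**d["heterogeneity"]),
            accounting=dict(d["accounting"]),
            outcome_type=d["outcome_type"],
            notice=d.get("notice"),
            seed=d.get("seed"),
        )


def analyze_instruments(
    instruments: SummaryDataset,
    outcome: SummaryDataset,
    proxies: Iterable[ProxyEntry] = (),
    r2_min: float = 0.9,
    outcome_type: str = "binary",
    n_boot: int = 1000,
    seed: int = 0,
    policy: HarmonizationPolicy = HarmonizationPolicy(),
) -> tuple[ResultsTable, list[HarmonizedInstrument]]:
    """Core analysis on already-selected instruments (no file I/O).

    The pipeline entry point :func:`run_analysis` is a thin file-reading
    wrapper around this; calling the estimators directly on the returned
    harmonized instruments reproduces the table exactly (no hidden state).
    """
    n_selected = len(instruments)
    proxied_ds, sub_log = substitute_proxies(instruments, outcome, proxies, r2_min)
    n_proxied = sum(1 for e in sub_log if e.action == "proxied")
    n_dropped_proxy = sum(1 for e in sub_log if e.action == "dropped")

    harmonized = harmonize_datasets(proxied_ds, outcome, policy)
    usable = [h for h in harmonized if h.action != "dropped"]
    n_dropped_harm = len(harmonized) - len(usable)
    accounting = {
        "selected": n_selected,
        "proxied": n_proxied,
        "dropped_proxy": n_dropped_proxy,
        "dropped_harmonization": n_dropped_harm,
        "analyzed": len(usable),
    }
    if not usable:
        raise EmptyInstrumentError(
            f"no instrument survived proxy substitution and harmonization "
            f"(accounting: {accounting})"
        )

    scale = LOG_ODDS if outcome_type == "binary" else LINEAR
    ivw, het = ivw_estimate(usable, scale=scale)
    rows = [ivw]
    notice = None
    if len(usable) >= MIN_EGGER_INSTRUMENTS:
        rows.append(weighted_median_estimate(usable, n_boot=n_boot, seed=seed, scale=scale))
        slope, intercept = egger_estimate(orient_for_egger(usable), scale=scale)
        rows.extend([slope, intercept])
    else:
        notice = (
            f"only {len(usable)} instrument(s) survived; MR-Egger and the "
            f"weighted median need >= {MIN_EGGER_INSTRUMENTS}, reporting IVW only"
        )
    rows.sort(key=lambda r: _METHOD_ORDER.index(r.method))
    or_rows = [to_odds_ratio(r) for r in rows] if outcome_type == "binary" else []
    table = ResultsTable(
        rows=rows,
        heterogeneity=het,
        accounting=accounting,
        outcome_type=outcome_type,
        or_rows=or_rows,
        notice=notice,
        seed=seed,
    )
    return table, harmonized


def run_analysis(config: AnalysisConfig) -> ResultsTable:
    """Run the full pipeline from summary-statistic files per ``config``.

    When ``config.output_dir`` is set, writes ``results.tsv``,
    ``results.md``, ``results.json``, ``harmonization.tsv`` and ``run.log``
    there.
    """
    exposure = read_summary_table(config.exposure_path, trait_name="exposure")
    outcome = read_summary_table(
        config.outcome_path, trait_name="outcome", trait_type=config.outcome_type
    )
    proxies = read_proxy_table(config.proxy_path) if config.proxy_path else []
    instruments = select_instruments(exposure, config.p_threshold)
    table, harmonized = analyze_instruments(
        instruments,
        outcome,
        proxies=proxies,
        r2_min=config.r2_min,
        outcome_type=config.outcome_type,
        n_boot=config.n_boot,
        seed=config.seed,
        policy=config.policy(),
    )
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.tsv").write_text(format_results(table, "tsv"))
        (out / "results.md").write_text(format_results(table, "markdown"))
        (out / "results.json").write_text(format_results(table, "json"))
        harmonization_report(harmonized).to_csv(out / "harmonization.tsv", sep="\t", index=False)
        (out / "run.log").write_text(_run_log(config, table))
    return table


def _run_log(config: AnalysisConfig, table: ResultsTable) -> str:
    lines = [
        f"tsmr {__version__}",
        f"exposure: {config.exposure_path}",
        f"outcome: {config.outcome_path} ({config.outcome_type})",
        f"proxies: {config.proxy_path or '(none)'} (r2 >= {config.r2_min})",
        f"p threshold: {config.p_threshold:g}",
        f"seed: {config.seed}  n_boot: {config.n_boot}",
        "instrument accounting: "
        + ", ".join(f"{k}={v}" for k, v in table.accounting.items()),
    ]
    if table.notice:
        lines.append(f"notice: {table.notice}")
    return "\n".join(lines) + "\n"


_METHOD_LABELS = {
    "ivw": "IVW",
    "weighted_median": "Weighted median",
    "egger_slope": "MR-Egger slope",
    "egger_intercept": "MR-Egger intercept",
}


def _display_rows(table: ResultsTable) -> list[MREstimate]:
    return table.or_rows if table.outcome_type == "binary" else table.rows


def format_results(table: ResultsTable, style: str = "markdown") -> str:
    """Render a results table as TSV, markdown, or lossless JSON.

    TSV and markdown round estimates to 3 decimals and I² to a whole
    percent; binary outcomes are shown on the odds-ratio scale with the
    p-value from the log-odds test.
    """
    if style == "json":
        return json.dumps(table.to_dict(), indent=2)
    rows = _display_rows(table)
    effect_col = "OR" if table.outcome_type == "binary" else "beta"
    header = ["Method", effect_col, "95% CI", "P value"]
    body = [
        [
            _METHOD_LABELS[r.method],
            f"{r.estimate:.3f}",
            f"{r.ci_low:.3f}, {r.ci_high:.3f}",
            f"{r.pval:.3g}",
        ]
        for r in rows
    ]
    i2 = f"{round(table.heterogeneity.i2)}%"
    acc = table.accounting
    footer = (
        f"Heterogeneity I2 = {i2} (Q = {table.heterogeneity.Q:.3f}, "
        f"df = {table.heterogeneity.df}); instruments: {acc['selected']} selected, "
        f"{acc['proxied']} proxied, {acc['dropped_proxy'] + acc['dropped_harmonization']} "
        f"dropped, {acc['analyzed']} analyzed"
    )
    if style == "tsv":
        lines = ["\t".join(header)] + ["\t".join(b) for b in body]
        lines.append(f"# {footer}")
        if table.notice:
            lines.append(f"# NOTE: {table.notice}")
        return "\n".join(lines) + "\n"
    if style == "markdown":
        widths = [max(len(h), *(len(b[i]) for b in body)) for i, h in enumerate(header)]
        def fmt(cells):
            return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
        lines = [fmt(header), "|" + "|".join("-" * (w + 2) for w in widths) + "|"]
        lines += [fmt(b) for b in body]
        lines.append("")
        lines.append(footer)
        if table.notice:
            lines.append(f"NOTE: {table.notice}")
        return "\n".join(lines) + "\n"
    raise ValidationError(f"unknown style {style!r}; use tsv|markdown|json")
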