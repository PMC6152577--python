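"""Reading, writing and filtering GWAS summary-statistic tables.

A summary dataset is one GWAS's per-SNP association table: identifier,
effect/other allele, effect-allele frequency, beta, standard error, p-value
and sample size.  Binary traits carry betas on the log-odds scale,
continuous traits on their raw (or trait-SD) scale.  This module also
implements instrument selection by p-value threshold and LD-proxy
substitution for instruments missing from the outcome dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import EmptyInstrumentError, FormatError, ValidationError

VALID_ALLELES = frozenset("ACGT")

#: Default column names of the on-disk tab-separated layout, keyed by field.
DEFAULT_DIALECT: dict[str, str] = {
    "snp_id": "SNP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

_MANDATORY_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association statistics in one GWAS."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: effect allele {self.effect_allele!r} not in A/C/G/T"
            )
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: other allele {self.other_allele!r} not in A/C/G/T"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValidationError(f"{self.snp_id}: se must be finite and > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValidationError(f"{self.snp_id}: p-value {self.pval} outside (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValidationError(f"{self.snp_id}: EAF {self.eaf} outside (0, 1)")
        if self.n is not None and self.n <= 0:
            raise ValidationError(f"{self.snp_id}: sample size must be positive")


@dataclass(frozen=True)
class ProxyEntry:
    """One LD-proxy candidate: ``proxy_snp`` tags ``query_snp`` at the given r²."""

    query_snp: str
    proxy_snp: str
    r2: float
    distance: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.r2 <= 1):
            raise ValidationError(f"proxy r² {self.r2} outside [0, 1]")
        if self.query_snp == self.proxy_snp:
            raise ValidationError(f"proxy entry maps {self.query_snp} to itself")


@dataclass
class SummaryDataset:
    """An ordered collection of :class:`SummaryRecord` with trait metadata."""

    records: list[SummaryRecord]
    trait_name: str = ""
    trait_type: str = "continuous"  # "binary" or "continuous"
    sample_size: int | None = None
    #: (row index, reason) pairs for rows rejected at parse time.
    rejected_rows: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ValidationError(f"trait_type must be binary|continuous, got {self.trait_type!r}")
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate SNP ids in dataset: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def snp_ids(self) -> set[str]:
        return {r.snp_id for r in self.records}

    def get(self, snp_id: str) -> SummaryRecord:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        raise KeyError(snp_id)


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_summary_table(
    path,
    dialect: Mapping[str, str] | None = None,
    trait_name: str = "",
    trait_type: str = "continuous",
    sample_size: int | None = None,
) -> SummaryDataset:
    """Read a tab-separated summary-statistic table into a :class:`SummaryDataset`.

    ``dialect`` maps record field names to the file's column names; unmapped
    fields fall back to :data:`DEFAULT_DIALECT`.  The optional EAF and N
    columns may be absent entirely or coded ``NA``.  Rows violating the
    per-record invariants are rejected individually and reported in
    ``dataset.rejected_rows``; a missing mandatory column raises
    :class:`~tsmr.errors.FormatError`.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(
        path, sep="\t", na_values=["NA"], dtype={cols["snp_id"]: str},
        float_precision="round_trip",
    )
    missing = [cols[f] for f in _MANDATORY_FIELDS if cols[f] not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    has_eaf = cols["eaf"] in df.columns
    has_n = cols["n"] in df.columns

    records: list[SummaryRecord] = []
    rejected: list[tuple[int, str]] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        try:
            eaf = _parse_optional_float(row[cols["eaf"]]) if has_eaf else None
            n_val = _parse_optional_float(row[cols["n"]]) if has_n else None
            rec = SummaryRecord(
                snp_id=str(row[cols["snp_id"]]),
                effect_allele=str(row[cols["effect_allele"]]).upper(),
                other_allele=str(row[cols["other_allele"]]).upper(),
                beta=float(row[cols["beta"]]),
                se=float(row[cols["se"]]),
                pval=float(row[cols["pval"]]),
                eaf=eaf,
                n=int(n_val) if n_val is not None else None,
            )
        except (ValidationError, ValueError, TypeError) as exc:
            rejected.append((idx, str(exc)))
            continue
        records.append(rec)
    return SummaryDataset(
        records=records,
        trait_name=trait_name,
        trait_type=trait_type,
        sample_size=sample_size,
        rejected_rows=rejected,
    )


def write_summary_table(dataset: SummaryDataset, path) -> None:
    """Write a dataset in the default tab-separated dialect (missing values as ``NA``)."""
    df = pd.DataFrame(
        {
            "SNP": [r.snp_id for r in dataset],
            "EA": [r.effect_allele for r in dataset],
            "OA": [r.other_allele for r in dataset],
            "EAF": [r.eaf if r.eaf is not None else "NA" for r in dataset],
            "BETA": [repr(r.beta) for r in dataset],
            "SE": [repr(r.se) for r in dataset],
            "P": [repr(r.pval) for r in dataset],
            "N": [r.n if r.n is not None else "NA" for r in dataset],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def select_instruments(dataset: SummaryDataset, p_threshold: float) -> SummaryDataset:
    """Keep records with ``pval`` strictly below ``p_threshold``, preserving order.

    Raises :class:`~tsmr.errors.EmptyInstrumentError` when nothing survives,
    since no MR estimator can run on zero instruments.
    """
    if not (0 < p_threshold < 1):
        raise ValidationError(f"p threshold {p_threshold} outside (0, 1)")
    kept = [r for r in dataset if r.pval < p_threshold]
    if not kept:
        raise EmptyInstrumentError(
            f"no SNP in {dataset.trait_name or 'dataset'} passes P < {p_threshold:g}"
        )
    return SummaryDataset(
        records=kept,
        trait_name=dataset.trait_name,
        trait_type=dataset.trait_type,
        sample_size=dataset.sample_size,
    )


@dataclass(frozen=True)
class SubstitutionEvent:
    """One entry of the proxy-substitution log."""

    snp_id: str
    action: str  # "kept" | "proxied" | "dropped"
    proxy_snp: str | None = None
    r2: float | None = None


def substitute_proxies(
    instruments: SummaryDataset,
    outcome: SummaryDataset,
    proxies: Iterable[ProxyEntry] = (),
    r2_min: float = 0.9,
) -> tuple[SummaryDataset, list[SubstitutionEvent]]:
    """Replace instruments absent from the outcome dataset by their best LD proxy.

    An instrument missing from ``outcome`` is replaced by the highest-r² proxy
    (r² >= ``r2_min``) that *is* present in the outcome dataset; ties break by
    smallest distance then lexicographic proxy ID.  The proxy inherits the
    instrument's exposure statistics under its own ID (r² >= 0.9 means the two
    variants tag the same signal).  Instruments with no qualifying proxy are
    dropped.  Every decision is logged; drops are never fatal here.
    """
    if not (0 < r2_min <= 1):
        raise ValidationError(f"r2_min {r2_min} outside (0, 1]")
    outcome_ids = outcome.snp_ids()
    by_query: dict[str, list[ProxyEntry]] = {}
    for p in proxies:
        by_query.setdefault(p.query_snp, []).append(p)

    kept: list[SummaryRecord] = []
    log: list[SubstitutionEvent] = []
    for rec in instruments:
        if rec.snp_id in outcome_ids:
            kept.append(rec)
            log.append(SubstitutionEvent(rec.snp_id, "kept"))
            continue
        candidates = [
            p
            for p in by_query.get(rec.snp_id, [])
            if p.r2 >= r2_min and p.proxy_snp in outcome_ids
        ]
        if not candidates:
            log.append(SubstitutionEvent(rec.snp_id, "dropped"))
            continue
        best = min(
            candidates,
            key=lambda p: (
                -p.r2,
                p.distance if p.distance is not None else math.inf,
                p.proxy_snp,
            ),
        )
        kept.append(replace(rec, snp_id=best.proxy_snp))
        log.append(
            SubstitutionEvent(rec.snp_id, "proxied", proxy_snp=best.proxy_snp, r2=best.r2)
        )
    return (
        SummaryDataset(
            records=kept,
            trait_name=instruments.trait_name,
            trait_type=instruments.trait_type,
            sample_size=instruments.sample_size,
        ),
        log,
    )


def read_proxy_table(path) -> list[ProxyEntry]:
    """Read a proxy table (TSV with columns query, proxy, r2 and optional distance)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    needed = {"query", "proxy", "r2"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: proxy table needs columns {sorted(needed)}")
    entries = []
    for row in df.itertuples(index=False):
        d = _parse_optional_float(getattr(row, "distance", None))
        entries.append(
            ProxyEntry(
                query_snp=str(row.query),
                proxy_snp=str(row.proxy),
                r2=float(row.r2),
                distance=int(d) if d is not None else None,
            )
        )
    return entries


def write_proxy_table(proxies: Sequence[ProxyEntry], path) -> None:
    df = pd.DataFrame(
        {
            "query": [p.query_snp for p in proxies],
            "proxy": [p.proxy_snp for p in proxies],
            "r2": [p.r2 for p in proxies],
            "distance": [p.distance if p.distance is not None else "NA" for p in proxies],
        }
    )
    df.to_csv(path, sep="\t", index=False)
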