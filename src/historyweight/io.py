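"""Readers and writers for the pipeline's tab-separated table dialects.

The domain data is tabular clinical metadata, not sequence data; no
standard bioinformatics container carries per-proband family history, so
a small documented TSV dialect is defined here.

Proband table columns (header row required):

    proband_id  test_date  ethnicity  current_age  personal  relatives  findings

``test_date`` is ISO 8601 (YYYY-MM-DD).  ``personal`` holds
semicolon-separated ``site@age`` tokens (empty = no diagnoses);
``relatives`` holds ``degree:site@age`` tokens; ``findings`` holds
``gene=class`` tokens.  A proband whose history was not provided is
encoded with the sentinel ``NA`` in both the personal and relatives
columns.  Variant tables have columns ``variant_id  gene  truth_label
carrier_ids`` with comma-separated carrier ids (a repeated id marks a
simulated duplicate); truth tables have ``proband_id  true_carrier_gene
family_id``.  Lines starting with ``#`` are provenance comments
(config digest, seed) and are skipped on read.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import yaml

from .cohort import (
    CancerDiagnosis,
    ClinicalHistory,
    Degree,
    Ethnicity,
    FindingClass,
    Gene,
    GeneConfig,
    DEFAULT_GENE_CONFIGS,
    Proband,
    RelativeDiagnosis,
    Site,
    VariantObservation,
)
from .controls import MatchingPolicy
from .errors import ParseError
from .experiments import SimVariantConfig, TrialPolicy
from .synthetic import SimCohortConfig, SimTruthRecord
from .weighting import (
    CellStats,
    ConditionalProbabilityTable,
    HistoryBinKey,
    ScoringPolicy,
)

__all__ = [
    "read_proband_table",
    "write_proband_table",
    "read_variant_table",
    "write_variant_table",
    "read_truth_table",
    "write_truth_table",
    "read_table",
    "write_table",
    "RunConfig",
    "config_digest",
]

_MISSING = "NA"
PROBAND_COLUMNS = (
    "proband_id", "test_date", "ethnicity", "current_age", "personal", "relatives", "findings",
)


def config_digest(obj) -> str:
    """Stable short digest of a configuration mapping, for provenance."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(meta: Optional[Mapping]) -> list[str]:
    if not meta:
        return []
    return [f"# {k}={v}" for k, v in meta.items()]


def _site_age(token: str, path, lineno, column: str) -> tuple[Site, int]:
    try:
        site_s, age_s = token.split("@")
        return Site(site_s), int(age_s)
    except (ValueError, KeyError) as exc:
        raise ParseError(f"bad {column} token {token!r}", path, lineno) from exc


def _format_history(h: ClinicalHistory) -> tuple[str, str]:
    if h.missing:
        return _MISSING, _MISSING
    personal = ";".join(f"{d.site.value}@{d.age_at_diagnosis}" for d in h.personal)
    relatives = ";".join(
        f"{d.degree.value}:{d.site.value}@{d.age_at_diagnosis}" for d in h.relatives
    )
    return personal, relatives


def write_proband_table(
    probands: Iterable[Proband],
    path: Union[str, Path],
    meta: Optional[Mapping] = None,
) -> None:
    lines = _provenance(meta)
    lines.append("\t".join(PROBAND_COLUMNS))
    for p in probands:
        personal, relatives = _format_history(p.history)
        findings = ";".join(f"{g.value}={c.value}" for g, c in sorted(p.findings.items()))
        lines.append(
            "\t".join(
                (
                    p.proband_id,
                    p.test_date.isoformat(),
                    p.ethnicity.value,
                    str(p.history.current_age),
                    personal,
                    relatives,
                    findings,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _data_lines(path: Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_proband_table(path: Union[str, Path]) -> list[Proband]:
    path = Path(path)
    rows = _data_lines(path)
    try:
        header_line = next(rows)
    except StopIteration:
        raise ParseError("empty proband table", path) from None
    header = tuple(header_line[1].split("\t"))
    if header != PROBAND_COLUMNS:
        raise ParseError(
            f"bad header {header!r}, expected {PROBAND_COLUMNS!r}", path, header_line[0]
        )
    out: list[Proband] = []
    for lineno, line in rows:
        fields = line.split("\t")
        if len(fields) != len(PROBAND_COLUMNS):
            raise ParseError(f"expected {len(PROBAND_COLUMNS)} columns, got {len(fields)}", path, lineno)
        pid, date_s, eth_s, age_s, personal_s, relatives_s, findings_s = fields
        try:
            test_date = datetime.date.fromisoformat(date_s)
        except ValueError as exc:
            raise ParseError(f"bad test_date {date_s!r}", path, lineno) from exc
        try:
            ethnicity = Ethnicity(eth_s)
        except ValueError as exc:
            raise ParseError(f"unknown ethnicity {eth_s!r}", path, lineno) from exc
        try:
            current_age = int(age_s)
        except ValueError as exc:
            raise ParseError(f"bad current_age {age_s!r}", path, lineno) from exc
        if personal_s == _MISSING or relatives_s == _MISSING:
            history = ClinicalHistory(current_age=current_age, missing=True)
        else:
            personal = tuple(
                CancerDiagnosis(*_site_age(tok, path, lineno, "personal"))
                for tok in personal_s.split(";")
                if tok
            )
            relatives = []
            for tok in relatives_s.split(";"):
                if not tok:
                    continue
                try:
                    degree_s, rest = tok.split(":", 1)
                    degree = Degree(degree_s)
                except ValueError as exc:
                    raise ParseError(f"bad relatives token {tok!r}", path, lineno) from exc
                site, age = _site_age(rest, path, lineno, "relatives")
                relatives.append(RelativeDiagnosis(degree, site, age))
            history = ClinicalHistory(
                current_age=current_age, personal=personal, relatives=tuple(relatives)
            )
        findings = {}
        for tok in findings_s.split(";"):
            if not tok:
                continue
            try:
                gene_s, cls_s = tok.split("=")
                findings[Gene(gene_s)] = FindingClass(cls_s)
            except ValueError as exc:
                raise ParseError(f"bad findings token {tok!r}", path, lineno) from exc
        try:
            out.append(Proband(pid, test_date, ethnicity, history, findings))
        except (TypeError, ValueError) as exc:
            raise ParseError(str(exc), path, lineno) from exc
    return out


# ---------------------------------------------------------------------------
# Variant and truth tables

VARIANT_COLUMNS = ("variant_id", "gene", "truth_label", "carrier_ids")


def write_variant_table(
    variants: Iterable[VariantObservation],
    path: Union[str, Path],
    meta: Optional[Mapping] = None,
) -> None:
    lines = _provenance(meta)
    lines.append("\t".join(VARIANT_COLUMNS))
    for v in variants:
        lines.append(
            "\t".join(
                (v.variant_id, v.gene.value, v.truth_label or "", ",".join(v.carrier_ids))
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_variant_table(path: Union[str, Path]) -> list[VariantObservation]:
    path = Path(path)
    rows = _data_lines(path)
    try:
        header_line = next(rows)
    except StopIteration:
        raise ParseError("empty variant table", path) from None
    if tuple(header_line[1].split("\t")) != VARIANT_COLUMNS:
        raise ParseError("bad variant table header", path, header_line[0])
    out = []
    for lineno, line in rows:
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(f"expected 4 columns, got {len(fields)}", path, lineno)
        vid, gene_s, label_s, carriers_s = fields
        carrier_ids = tuple(c for c in carriers_s.split(",") if c)
        if not carrier_ids:
            raise ParseError("empty carrier_ids", path, lineno)
        # repeated ids in the serialized list are simulated duplicates
        seen: set[str] = set()
        flags = []
        for cid in carrier_ids:
            flags.append(cid in seen)
            seen.add(cid)
        try:
            out.append(
                VariantObservation(
                    vid,
                    Gene(gene_s),
                    carrier_ids,
                    truth_label=label_s or None,
                    duplicate_flags=tuple(flags) if any(flags) else None,
                )
            )
        except ValueError as exc:
            raise ParseError(str(exc), path, lineno) from exc
    return out


TRUTH_COLUMNS = ("proband_id", "true_carrier_gene", "family_id")


def write_truth_table(
    truth: Iterable[SimTruthRecord], path: Union[str, Path], meta: Optional[Mapping] = None
) -> None:
    lines = _provenance(meta)
    lines.append("\t".join(TRUTH_COLUMNS))
    for t in truth:
        gene = t.true_carrier_gene.value if t.true_carrier_gene else ""
        lines.append("\t".join((t.proband_id, gene, t.family_id)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_table(path: Union[str, Path]) -> list[SimTruthRecord]:
    path = Path(path)
    rows = _data_lines(path)
    try:
        header_line = next(rows)
    except StopIteration:
        raise ParseError("empty truth table", path) from None
    if tuple(header_line[1].split("\t")) != TRUTH_COLUMNS:
        raise ParseError("bad truth table header", path, header_line[0])
    out = []
    for lineno, line in rows:
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(f"expected 3 columns, got {len(fields)}", path, lineno)
        pid, gene_s, fam = fields
        out.append(SimTruthRecord(pid, Gene(gene_s) if gene_s else None, fam))
    return out


# ---------------------------------------------------------------------------
# Conditional probability tables

_TABLE_KEY_FIELDS = ("age_bin", "crc", "ec", "ov", "fam_crc", "fam_ec", "fam_ov")


def write_table(
    table: ConditionalProbabilityTable, path: Union[str, Path], meta: Optional[Mapping] = None
) -> None:
    """Persist a table so scoring is reproducible across runs."""
    lines = _provenance(meta)
    lines.append(
        f"# gene={table.gene.value}\tprior={table.prior!r}\tpseudocount={table.pseudocount!r}"
    )
    lines.append("\t".join(_TABLE_KEY_FIELDS + ("carriers", "total", "q")))
    for key in sorted(table.cells):
        cell = table.cells[key]
        lines.append(
            "\t".join(
                [str(x) for x in key] + [str(cell.carrier_count), str(cell.total_count), repr(cell.q)]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_table(path: Union[str, Path]) -> ConditionalProbabilityTable:
    path = Path(path)
    gene = prior = pseudocount = None
    cells = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("# gene="):
                parts = dict(tok.split("=", 1) for tok in line[2:].split("\t"))
                gene = Gene(parts["gene"])
                prior = float(parts["prior"])
                pseudocount = float(parts["pseudocount"])
                continue
            if line.startswith("#") or line.startswith("age_bin"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_TABLE_KEY_FIELDS) + 3:
                raise ParseError("bad table row", path, lineno)
            key = HistoryBinKey(*(int(x) for x in fields[:7]))
            cells[key] = CellStats(int(fields[7]), int(fields[8]), float(fields[9]))
    if gene is None or prior is None:
        raise ParseError("table is missing its '# gene=...' header", path)
    return ConditionalProbabilityTable(gene, cells, prior, pseudocount)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Structured run configuration for the command-line front end.

    Carries every policy plus a master seed; all pipeline randomness is
    derived from that seed via named substreams, and every output file
    embeds the config digest and seed for reproducibility.
    """

    seed: int = 0
    weak_counts: bool = True
    n_composites: int = 1000
    genes: tuple[Gene, ...] = tuple(Gene)
    gene_configs: Mapping[Gene, GeneConfig] = field(
        default_factory=lambda: dict(DEFAULT_GENE_CONFIGS)
    )
    scoring: ScoringPolicy = field(default_factory=ScoringPolicy)
    matching: MatchingPolicy = field(default_factory=MatchingPolicy)
    trials: TrialPolicy = field(default_factory=TrialPolicy)
    sim_cohort: SimCohortConfig = field(default_factory=SimCohortConfig)
    sim_variants: SimVariantConfig = field(default_factory=SimVariantConfig)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        kwargs = {}
        for key in ("seed", "weak_counts", "n_composites"):
            if key in data:
                kwargs[key] = data[key]
        if "genes" in data:
            kwargs["genes"] = tuple(Gene(g) for g in data["genes"])
        if "gene_configs" in data:
            cfgs = dict(DEFAULT_GENE_CONFIGS)
            for gene_s, over in data["gene_configs"].items():
                gene = Gene(gene_s)
                base = cfgs[gene]
                cfgs[gene] = GeneConfig(
                    gene,
                    over.get("prior_carrier_probability", base.prior_carrier_probability),
                    over.get("variant_pathogenic_prevalence", base.variant_pathogenic_prevalence),
                    over.get("sd_benign", base.sd_benign),
                    over.get("sd_pathogenic", base.sd_pathogenic),
                )
            kwargs["gene_configs"] = cfgs
        for key, cls_ in (
            ("scoring", ScoringPolicy),
            ("matching", MatchingPolicy),
            ("trials", TrialPolicy),
            ("sim_variants", SimVariantConfig),
        ):
            if key in data:
                kwargs[key] = cls_(**data[key])
        if "sim_cohort" in data:
            sub = dict(data["sim_cohort"])
            if "carrier_fraction_per_gene" in sub:
                sub["carrier_fraction_per_gene"] = {
                    Gene(g): f for g, f in sub["carrier_fraction_per_gene"].items()
                }
            for key in ("test_date_start", "test_date_end"):
                if key in sub and isinstance(sub[key], str):
                    sub[key] = datetime.date.fromisoformat(sub[key])
            kwargs["sim_cohort"] = SimCohortConfig(**sub)
        return cls(**kwargs)

    def digest(self) -> str:
        return config_digest(
            {
                "seed": self.seed,
                "weak_counts": self.weak_counts,
                "n_composites": self.n_composites,
                "genes": [g.value for g in self.genes],
                "gene_configs": {
                    g.value: [c.prior_carrier_probability, c.variant_pathogenic_prevalence,
                              c.sd_benign, c.sd_pathogenic]
                    for g, c in self.gene_configs.items()
                },
                "scoring": [self.scoring.max_probands, self.scoring.min_probands, self.scoring.pseudocount],
                "matching": [self.matching.window_halfwidth_days,
                             self.matching.min_controls_per_proband, self.matching.n_composites],
                "trials": [self.trials.n_trials, self.trials.start_probands,
                           self.trials.growth_factor, self.trials.pool_cap],
                "sim_cohort_seed": self.sim_cohort.seed,
                "sim_cohort_n": self.sim_cohort.n_probands,
            }
        )

    def meta(self) -> dict:
        return {"config_digest": self.digest(), "seed": self.seed}
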