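"""End-to-end analysis pipeline: generate/load -> score -> screen -> test.

Per outcome, the decision flow mirrors the study design for a candidate
SNP and cognitive endophenotypes:

1. Kolmogorov-Smirnov (Lilliefors) normality screen on the outcome;
2. normally distributed outcomes go to parametric ANCOVA (genotype
   carrier class and affection status as fixed factors, their
   interaction, total BPRS as covariate, Type III SS);
3. non-normal outcomes are first log-transformed and re-screened; if
   still non-normal they receive genotype-permutation empirical
   p-values, run twice — once restricted to completely asymptomatic
   participants (BPRS < 27) and once on everyone with BPRS as covariate
   — and the two variants are reported side by side, never pooled.

Genotype coding always collapses the rare homozygote with the
heterozygotes into one carrier class.  Participants without a genotype
call are excluded from association analyses but retained (flagged) in
the demographic table; every filtering step is counted in the run log.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from ._seeds import child_rng, child_seed
from .cohort import (CohortConfig, block_scores_from_matrix, carrier_class,
                     generate_cohort, generate_cpt_matrix, generate_phenotypes,
                     OUTCOME_REGISTRY)
from .errors import BoundedSearchError, CogassocError, ConfigurationError
from .glm import AnovaResult, ModelSpec, fit_anova, fit_rm_anova, \
    ks_normality, polynomial_contrast_test
from .permutation import PermutationPlan, apply_variant, permute_pvalue
from .power import PowerSpec, cohens_d, d_to_r2, hwe_test, \
    sample_size_for_power

log = logging.getLogger(__name__)

__all__ = ["OutcomeSpec", "RunConfig", "RunReport", "run_pipeline",
           "read_genotypes", "demographics_table"]

CPT_OUTCOMES = ("sensitivity", "false_alarm", "hit_rate", "criterion")


@dataclass(frozen=True)
class OutcomeSpec:
    """One analyzed outcome.

    ``block_structured`` outcomes refer to four per-block columns
    ``<name>_b1 .. <name>_b4``; the univariate association test then runs
    on the final block (where a vigilance deficit is largest) and a
    repeated-measures ANCOVA plus linear block-trend contrast are added.
    """

    name: str
    path: str = "auto"  # auto | parametric | permutation
    block_structured: bool = False

    def __post_init__(self):
        if self.path not in ("auto", "parametric", "permutation"):
            raise ConfigurationError(f"unknown analysis path {self.path!r}")


def default_outcomes() -> tuple[OutcomeSpec, ...]:
    cpt = tuple(OutcomeSpec(name, path="permutation", block_structured=True)
                for name in CPT_OUTCOMES)
    rest = tuple(OutcomeSpec(name) for name in OUTCOME_REGISTRY)
    return cpt + rest


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration: a synthetic cohort or observed tables."""

    cohort: CohortConfig | None = None
    participants_tsv: str | None = None
    phenotypes_tsv: str | None = None
    block_scores_tsv: str | None = None  # wide format (id + <name>_b1..4)
    outcomes: tuple[OutcomeSpec, ...] = field(default_factory=default_outcomes)
    n_permutations: int = 10_000
    permutation_scope: str = "unrestricted"
    sensitivity_method: str = "nonparametric"
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if self.cohort is None and self.participants_tsv is None:
            raise ConfigurationError(
                "either a cohort config or observed tables are required")


@dataclass
class RunReport:
    """Everything one reproducible run produced."""

    seed: int
    stage_seeds: dict
    demographics: pd.DataFrame
    hwe: dict
    normality: pd.DataFrame
    results: list
    effect_sizes: pd.DataFrame
    power_table: pd.DataFrame
    filter_log: dict
    versions: dict

    def to_payload(self) -> dict:
        """JSON-ready payload (stable ordering, no timestamps)."""
        return {
            "seed": self.seed,
            "stage_seeds": self.stage_seeds,
            "demographics": self.demographics.to_dict(orient="records"),
            "hwe": self.hwe,
            "normality": self.normality.to_dict(orient="records"),
            "results": self.results,
            "effect_sizes": self.effect_sizes.to_dict(orient="records"),
            "power_table": self.power_table.to_dict(orient="records"),
            "filter_log": self.filter_log,
            "versions": self.versions,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_payload(), indent=2, sort_keys=True,
                          default=_json_default, **kw)

    def write(self, output_dir) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        self.demographics.to_csv(out / "demographics.tsv", sep="\t", index=False)
        self.normality.to_csv(out / "normality.tsv", sep="\t", index=False)
        self.effect_sizes.to_csv(out / "effect_sizes.tsv", sep="\t", index=False)
        self.power_table.to_csv(out / "power_table.tsv", sep="\t", index=False)
        rows = []
        for r in self.results:
            for t in r.get("tests", []):
                rows.append({"outcome": r["outcome"], **t})
        pd.DataFrame(rows).to_csv(out / "results.tsv", sep="\t", index=False)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"unserializable {type(o)}")


def _anova_record(r: AnovaResult) -> dict:
    d = {"kind": "anova", "term": r.term, "F": r.F, "df1": r.df1,
         "df2": r.df2, "p": r.p}
    if r.epsilon is not None:
        d.update(epsilon=r.epsilon, df1_gg=r.df1_gg, df2_gg=r.df2_gg,
                 p_gg=r.p_gg, mauchly_p=r.mauchly_p, corrected=r.corrected)
    return d


# ---------------------------------------------------------------------------
# I/O helpers

def read_genotypes(path, snp_id: str | None = None) -> pd.Series:
    """Genotypes as a Series indexed by sample id, values CC/CT/TT/missing.

    CSV/TSV input needs columns ``id`` and ``genotype``.  VCF input
    extracts the single site named ``snp_id`` (or the only record when the
    file holds exactly one); half-calls and no-calls map to 'missing'.
    """
    path = Path(path)
    if path.suffix.lower() in (".csv", ".tsv", ".txt"):
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep)
        if not {"id", "genotype"}.issubset(df.columns):
            raise CogassocError("genotype table needs 'id' and 'genotype' columns")
        if df["id"].duplicated().any():
            dup = df["id"][df["id"].duplicated()].iloc[0]
            raise CogassocError(f"duplicate sample id {dup!r}")
        geno = df.set_index("id")["genotype"].astype(str)
        bad = ~geno.isin(["CC", "CT", "TT", "missing"])
        geno[bad] = "missing"
        return geno
    return _read_vcf_genotypes(path, snp_id)


def _read_vcf_genotypes(path, snp_id: str | None) -> pd.Series:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(samples) != len(set(samples)):
        raise CogassocError("duplicate sample IDs in VCF header")
    record = None
    n_records = 0
    for v in vcf:
        n_records += 1
        if snp_id is None or v.ID == snp_id:
            record = v
            if snp_id is not None:
                break
    if record is None or (snp_id is None and n_records != 1):
        raise CogassocError(
            f"SNP {snp_id!r} not found (or VCF not single-site)")
    alleles = [record.REF] + list(record.ALT)
    calls = []
    for gt in record.genotypes:
        a = [x for x in gt[:-1]]
        if len(a) != 2 or any(x < 0 for x in a):
            calls.append("missing")
        else:
            calls.append("".join(sorted(alleles[x] for x in a)))
    return pd.Series(calls, index=samples, name="genotype")


def demographics_table(participants: pd.DataFrame) -> pd.DataFrame:
    """Mean (sd) of age, education and BPRS per status x genotype class."""
    df = participants.copy()
    carr = carrier_class(df["genotype"])
    df["genotype_class"] = np.select(
        [carr == 0, carr == 1], ["CC", "CT+TT"], default="missing")

    def _fmt(x: pd.Series) -> str:
        m = x.mean()
        if len(x) < 2:
            return f"{m:.2f} (—)"
        return f"{m:.2f} ({x.std(ddof=1):.2f})"

    rows = []
    for (status, gcls), sub in df.groupby(["status", "genotype_class"],
                                          sort=True):
        rows.append({
            "status": status, "genotype_class": gcls, "n": len(sub),
            "age": _fmt(sub["age"]), "education": _fmt(sub["education"]),
            "bprs": _fmt(sub["bprs"]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the pipeline

def _assemble(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    seeds = {}
    if config.cohort is not None:
        cohort_cfg = config.cohort
        participants = generate_cohort(cohort_cfg)
        seeds["cohort"] = cohort_cfg.seed
        cpt_rng = child_rng(config.seed, "cpt")
        seeds["cpt"] = child_seed(config.seed, "cpt")
        cpt = generate_cpt_matrix(participants, cohort_cfg, cpt_rng)
        blocks = block_scores_from_matrix(cpt, method=config.sensitivity_method)
        phen_rng = child_rng(config.seed, "phenotypes")
        seeds["phenotypes"] = child_seed(config.seed, "phenotypes")
        phen = generate_phenotypes(participants, cohort_cfg, phen_rng)
    else:
        participants = pd.read_csv(config.participants_tsv, sep="\t")
        phen = (pd.read_csv(config.phenotypes_tsv, sep="\t")
                if config.phenotypes_tsv else
                pd.DataFrame({"id": participants["id"]}))
        blocks = (pd.read_csv(config.block_scores_tsv, sep="\t")
                  if config.block_scores_tsv else
                  pd.DataFrame({"id": participants["id"]}))
    table = participants.merge(phen, on="id").merge(blocks, on="id")
    return participants, table, seeds


def _screen_normality(col: pd.Series) -> dict:
    D, p = ks_normality(col)
    rec = {"ks_D": D, "ks_p": p, "normal": p >= 0.05,
           "log_transformed": False}
    if not rec["normal"]:
        x = col.dropna()
        if (x > 0).all():
            D2, p2 = ks_normality(np.log(x))
            rec.update(log_ks_D=D2, log_ks_p=p2)
            if p2 >= 0.05:
                rec.update(normal=True, log_transformed=True)
    return rec


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full decision flow and assemble the run report.

    Reproducible end to end: all stage seeds derive from ``config.seed``
    (cohort generation keeps its own seed from the cohort config).
    Per-outcome failures are isolated and reported as skipped records.
    """
    participants, table, stage_seeds = _assemble(config)

    filter_log = {"n_total": len(table)}
    carr = carrier_class(table["genotype"])
    genotyped = table[carr.notna()].copy()
    genotyped["carrier"] = carr.dropna().astype(int).map(
        {0: "noncarrier", 1: "carrier"})
    filter_log["n_genotype_missing"] = int(len(table) - len(genotyped))
    filter_log["n_analyzed"] = len(genotyped)
    filter_log["n_carriers"] = int((genotyped["carrier"] == "carrier").sum())
    filter_log["n_bprs_ge_27"] = int((genotyped["bprs"] >= 27).sum())

    demographics = demographics_table(table)

    # HWE in unrelated participants (patients + controls; one per family)
    unrelated = genotyped[genotyped["status"].isin(["patient", "control"])]
    counts = (int((unrelated["genotype"] == "CC").sum()),
              int((unrelated["genotype"] == "CT").sum()),
              int((unrelated["genotype"] == "TT").sum()))
    try:
        h = hwe_test(counts)
        hwe = {"counts": counts, "allele_freq": h.allele_freq,
               "chi2": h.chi2, "p_chi2": h.p_chi2, "p_exact": h.p_exact}
    except CogassocError as e:
        hwe = {"counts": counts, "error": str(e)}

    carrier_q = filter_log["n_carriers"] / max(filter_log["n_analyzed"], 1)
    perm_seed = child_seed(config.seed, "permutation")
    stage_seeds["permutation"] = perm_seed

    normality_rows = []
    results = []
    es_rows = []
    power_rows = []

    for i_out, ospec in enumerate(config.outcomes):
        rec = {"outcome": ospec.name, "tests": []}
        try:
            col_name = (f"{ospec.name}_b4" if ospec.block_structured
                        else ospec.name)
            y = genotyped[col_name]
            screen = _screen_normality(y)
            normality_rows.append({"outcome": ospec.name,
                                   "column": col_name, **screen})
            path = ospec.path
            if path == "auto":
                path = "parametric" if screen["normal"] else "permutation"
            rec["path"] = path
            rec["column"] = col_name

            work = genotyped.copy()
            if path == "parametric" and screen["log_transformed"]:
                work[col_name] = np.log(work[col_name])

            if path == "parametric":
                spec = ModelSpec(outcome=col_name,
                                 between=("carrier", "status"),
                                 covariates=("bprs",))
                for r in fit_anova(work, spec):
                    rec["tests"].append(_anova_record(r))
            else:
                spec = ModelSpec(outcome=col_name,
                                 between=("carrier", "status"),
                                 covariates=(), interactions=False)
                for variant in ("asymptomatic_only", "bprs_covariate"):
                    plan = PermutationPlan(
                        n_permutations=config.n_permutations,
                        seed=child_seed(perm_seed, f"{ospec.name}:{variant}"),
                        scope=config.permutation_scope,
                        variant=variant, term="carrier")
                    pr = permute_pvalue(work, spec, plan)
                    rec["tests"].append({
                        "kind": "permutation", "term": "carrier",
                        "variant": variant, "F": pr.observed_F,
                        "empirical_p": pr.empirical_p,
                        "count_ge": pr.count_ge, "B": pr.n_permutations,
                        "n_used": pr.n_used})

            if ospec.block_structured:
                bcols = tuple(f"{ospec.name}_b{j}" for j in range(1, 5))
                rm_spec = ModelSpec(outcome=bcols,
                                    between=("carrier", "status"),
                                    covariates=("bprs",))
                sub = genotyped.dropna(subset=[*bcols, "carrier", "status",
                                               "bprs"])
                for r in fit_rm_anova(sub, rm_spec):
                    rec["tests"].append(_anova_record(r))
                tr = polynomial_contrast_test(genotyped, rm_spec, "carrier")
                rec["tests"].append(_anova_record(tr))

            # effect size and the power-table row it implies
            nc = genotyped.loc[genotyped["carrier"] == "noncarrier", col_name].dropna()
            ca = genotyped.loc[genotyped["carrier"] == "carrier", col_name].dropna()
            es = cohens_d(nc, ca)
            es_rows.append({"outcome": ospec.name, "column": col_name,
                            "d": es.d, "n_noncarrier": es.n0,
                            "n_carrier": es.n1, "pooled_sd": es.pooled_sd})
            r2 = d_to_r2(abs(es.d), carrier_q) if es.n1 >= 2 else float("nan")
            if np.isfinite(r2) and r2 > 0:
                try:
                    n_needed = sample_size_for_power(PowerSpec(r2=r2))
                except (BoundedSearchError, CogassocError):
                    n_needed = None
            else:
                n_needed = None
            power_rows.append({"outcome": ospec.name,
                               "n": int(es.n0 + es.n1),
                               "pct_variance_explained": 100.0 * r2,
                               "n_for_80pct_power": n_needed})
        except CogassocError as e:
            log.warning("outcome %s skipped: %s", ospec.name, e)
            rec["skipped"] = str(e)
        results.append(rec)

    versions = {"cogassoc": _pkg_version,
                "python": platform.python_version(),
                "numpy": np.__version__, "pandas": pd.__version__}

    report = RunReport(seed=config.seed, stage_seeds=stage_seeds,
                       demographics=demographics, hwe=hwe,
                       normality=pd.DataFrame(normality_rows),
                       results=results,
                       effect_sizes=pd.DataFrame(es_rows),
                       power_table=pd.DataFrame(power_rows),
                       filter_log=filter_log, versions=versions)
    if config.output_dir:
        report.write(config.output_dir)
    return report
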