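"""Full-analysis orchestration.

Runs the complete genetic-evaluation workflow over a pedigree/phenotype
pair: normal-score ordinal traits per site, fit every requested
variant x trait univariately, derive the genetic parameters (variance
components with SEs, heritability, Q_ST, breeding-value accuracy, AIC),
then the bivariate stage (all within-site trait pairs under two variants,
cross-site fits per trait), and finally the matrix-level comparisons
(Mantel test between the variants' correlation matrices, module
detection).  Every output is a CSV keyed back to a JSON run manifest
holding input digests, the seed and per-fit convergence status.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bivariate import fit_bivariate_cross_site, fit_bivariate_within_site
from .models import AnimalModelREML
from .networks import detect_modules, mantel_test
from .parameters import heritability_binary, heritability_normal, heritability_with_provenance, qst
from .pedigree import read_pedigree
from .transforms import normal_score

ORDINAL_SCALES = {"STR": 9, "MAL": 9, "BR": 9, "NR": 6}


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    seed: int
    version: str = __version__
    config_digest: str = ""
    input_digests: dict = field(default_factory=dict)
    fits: list = field(default_factory=list)

    def record(self, stage, site, trait, variant, converged, note=""):
        self.fits.append(
            dict(stage=stage, site=site, trait=trait, variant=variant,
                 converged=bool(converged), note=note)
        )

    def write(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def prepare_site_table(table: pd.DataFrame, ordinal_traits=(), binary_traits=()) -> pd.DataFrame:
    """Normal-score the ordinal traits of one site's table (whole site)."""
    out = table.copy()
    for tr in ordinal_traits:
        if tr in out.columns:
            out[tr] = normal_score(out[tr])
    return out


def run_univariate_suite(
    pedigree,
    tables_by_site: dict,
    traits,
    variants=("ablup_f", "ablup_r", "ablup_gc1", "ablup_gc2"),
    ordinal_traits=(),
    binary_traits=(),
    manifest: RunManifest | None = None,
    compute_pev: bool = True,
) -> pd.DataFrame:
    """Variance components, h2, accuracy, AIC per site x trait x variant.

    ABLUP-R rows additionally carry the provenance variance and Q_ST.
    Individual fit failures are recorded in the manifest and the run
    continues.
    """
    rows = []
    for site, table in sorted(tables_by_site.items()):
        prepared = prepare_site_table(table, ordinal_traits)
        for trait in traits:
            if trait not in prepared.columns or prepared[trait].notna().sum() == 0:
                continue
            for variant in variants:
                link = "logit" if trait in binary_traits else "identity"
                est = AnimalModelREML(
                    trait=trait, variant=variant, link=link, compute_pev=compute_pev
                )
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        est.fit(prepared, pedigree)
                except Exception as exc:  # keep the suite running
                    if manifest is not None:
                        manifest.record("univariate", site, trait, variant, False, repr(exc))
                    continue
                vc = est.varcomp_
                row = dict(site=site, trait=trait, variant=variant)
                for comp in ("provenance", "additive", "replicate", "set_within_rep", "residual", "theta"):
                    if comp in vc.components:
                        row[comp] = vc.components[comp]
                        row[f"{comp}_se"] = vc.se(comp)
                try:
                    if link == "logit":
                        h2 = heritability_binary(vc)
                    elif variant == "ablup_r":
                        h2 = heritability_with_provenance(vc)
                    else:
                        h2 = heritability_normal(vc)
                    row["h2"] = h2.value
                    row["h2_se"] = h2.se
                except ValueError:
                    pass
                if variant == "ablup_r":
                    try:
                        q = qst(vc)
                        row["qst"] = q.value
                        row["qst_se"] = q.se
                        row["qst_significant"] = q.significant
                    except ValueError:
                        pass
                if est.accuracy_ is not None:
                    row["accuracy"] = float(est.accuracy_.mean())
                row["loglik"] = est.loglik_
                row["aic"] = est.aic_
                row["converged"] = est.converged_
                rows.append(row)
                if manifest is not None:
                    manifest.record("univariate", site, trait, variant, est.converged_)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["site", "trait", "variant"]).reset_index(drop=True)
    return df


def correlation_matrix_from_pairs(pairs: pd.DataFrame, traits) -> pd.DataFrame:
    """Symmetric r_G matrix (unit diagonal) from the pairwise results."""
    M = pd.DataFrame(np.eye(len(traits)), index=list(traits), columns=list(traits))
    for _, r in pairs.iterrows():
        M.loc[r["trait_i"], r["trait_j"]] = M.loc[r["trait_j"], r["trait_i"]] = r["rg"]
    return M


def run_correlation_suite(
    pedigree,
    tables_by_site: dict,
    traits,
    variants=("ablup_f", "ablup_gc1"),
    ordinal_traits=(),
    cross_site: bool = True,
    mantel_permutations: int = 999,
    seed: int = 0,
    manifest: RunManifest | None = None,
) -> dict:
    """Bivariate stage: pairwise within-site r_G per variant, cross-site r_G
    per trait, Mantel comparison of the variants' matrices and module
    detection per matrix.

    Returns ``{"pairs": ..., "cross_site": ..., "mantel": ...,
    "modules": ...}`` DataFrames.
    """
    pair_rows, cross_rows, mantel_rows, module_rows = [], [], [], []
    matrices = {}
    sites = sorted(tables_by_site)
    for site in sites:
        prepared = prepare_site_table(tables_by_site[site], ordinal_traits)
        have = [t for t in traits if t in prepared.columns and prepared[t].notna().sum() > 0]
        for variant in variants:
            for ti, tj in itertools.combinations(have, 2):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        fit = fit_bivariate_within_site(prepared, ti, tj, variant, pedigree)
                    pair_rows.append(
                        dict(site=site, variant=variant, trait_i=ti, trait_j=tj,
                             rg=fit.rg.value, rg_se=fit.rg.se, converged=fit.converged)
                    )
                    if manifest is not None:
                        manifest.record("bivariate", site, f"{ti}/{tj}", variant, fit.converged)
                except Exception as exc:
                    if manifest is not None:
                        manifest.record("bivariate", site, f"{ti}/{tj}", variant, False, repr(exc))
            sub = [r for r in pair_rows if r["site"] == site and r["variant"] == variant]
            if sub and len(have) >= 3:
                M = correlation_matrix_from_pairs(pd.DataFrame(sub), have)
                matrices[(site, variant)] = M
                part = detect_modules(M)
                for t, m in part.assignment.items():
                    module_rows.append(
                        dict(site=site, variant=variant, trait=t, module=m, q_mod=part.q_mod)
                    )
        if all((site, v) in matrices for v in variants) and len(variants) == 2:
            stat, p = mantel_test(
                matrices[(site, variants[0])],
                matrices[(site, variants[1])],
                n_perm=mantel_permutations,
                seed=seed,
            )
            mantel_rows.append(
                dict(site=site, variant_a=variants[0], variant_b=variants[1],
                     mantel_r=stat, p_value=p, n_perm=mantel_permutations)
            )
    if cross_site and len(sites) == 2:
        ta, tb = tables_by_site[sites[0]], tables_by_site[sites[1]]
        pa = prepare_site_table(ta, ordinal_traits)
        pb = prepare_site_table(tb, ordinal_traits)
        for variant in variants:
            for trait in traits:
                if not (trait in pa.columns and trait in pb.columns):
                    continue
                if pa[trait].notna().sum() == 0 or pb[trait].notna().sum() == 0:
                    continue
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        fit = fit_bivariate_cross_site(pa, pb, trait, variant, pedigree)
                    cross_rows.append(
                        dict(trait=trait, variant=variant, site_a=sites[0], site_b=sites[1],
                             rg=fit.rg.value, rg_se=fit.rg.se, converged=fit.converged)
                    )
                    if manifest is not None:
                        manifest.record("cross_site", "both", trait, variant, fit.converged)
                except Exception as exc:
                    if manifest is not None:
                        manifest.record("cross_site", "both", trait, variant, False, repr(exc))
    return {
        "pairs": pd.DataFrame(pair_rows),
        "cross_site": pd.DataFrame(cross_rows),
        "mantel": pd.DataFrame(mantel_rows),
        "modules": pd.DataFrame(module_rows),
        "matrices": matrices,
    }


def ingest_study_workbook(path, mapping: dict):
    """Read an exported study workbook into (pedigree, per-site tables).

    ``mapping`` (from the run config) names the sheets and columns, e.g.::

        pedigree_sheet: pedigree
        phenotype_sheet: phenotypes
        columns:
          tree: TreeID
          dam: Mother
          provenance: Prov
          site: Site
          replicate: Rep
          set: Set
          control: Control
        traits: {DBH1: dbh11, STR1: str11}

    Unmapped required columns raise a mapping error listing the workbook's
    candidate column names.
    """
    from .pedigree import PedigreeRecord

    sheets = pd.read_excel(path, sheet_name=None, engine="openpyxl")
    ph_sheet = mapping.get("phenotype_sheet", "phenotypes")
    if ph_sheet not in sheets:
        raise KeyError(f"phenotype sheet {ph_sheet!r} not found; sheets: {sorted(sheets)}")
    ph = sheets[ph_sheet]
    cols = mapping.get("columns", {})
    required = ("tree", "site", "replicate", "set", "provenance")
    out = pd.DataFrame()
    for key in required + ("control",):
        src = cols.get(key, key)
        if src not in ph.columns:
            if key == "control":
                out[key] = ""
                continue
            raise KeyError(
                f"column for {key!r} ({src!r}) not in the workbook; candidates: "
                f"{list(ph.columns)}"
            )
        out[key] = ph[src]
    n_before = len(ph)
    traits = mapping.get("traits", {})
    for trait, src in traits.items():
        if src not in ph.columns:
            raise KeyError(
                f"trait column {src!r} (for {trait}) not in the workbook; candidates: "
                f"{list(ph.columns)}"
            )
        out[trait] = pd.to_numeric(ph[src], errors="coerce")
    assert len(out) == n_before
    out["tree"] = out["tree"].astype(str)

    ped_sheet = mapping.get("pedigree_sheet")
    records = []
    if ped_sheet and ped_sheet in sheets:
        pdf = sheets[ped_sheet]
        pcols = mapping.get("pedigree_columns", {})
        for _, r in pdf.iterrows():
            records.append(
                PedigreeRecord(
                    individual=str(r[pcols.get("individual", "individual")]),
                    dam=str(r.get(pcols.get("dam", "dam"), "") or ""),
                    sire=str(r.get(pcols.get("sire", "sire"), "") or ""),
                    provenance=str(r.get(pcols.get("provenance", "provenance"), "") or ""),
                )
            )
    else:
        # maternal pedigree reconstructed from the phenotype table
        dam_col = cols.get("dam")
        seen = {}
        for _, r in out.iterrows():
            dam = str(ph.loc[r.name, dam_col]) if dam_col and dam_col in ph.columns else ""
            prov = str(r["provenance"]) if pd.notna(r["provenance"]) else ""
            is_ctrl = str(r.get("control", "")) not in ("", "nan")
            if dam and dam not in seen and not is_ctrl:
                seen[dam] = PedigreeRecord(dam, provenance=prov)
            if r["tree"] not in seen:
                seen[r["tree"]] = PedigreeRecord(
                    r["tree"], dam=dam, provenance="" if is_ctrl else prov
                )
        records = list(seen.values())

    tables = {str(site): g.reset_index(drop=True) for site, g in out.groupby("site")}
    return records, tables


def run_pipeline(config: dict, out_dir, seed: int = 0) -> RunManifest:
    """Execute the stages requested in ``config`` and write all tables."""
    os.makedirs(out_dir, exist_ok=True)
    manifest = RunManifest(seed=seed)
    manifest.config_digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    ped_path = config["pedigree"]
    pheno_path = config["phenotypes"]
    manifest.input_digests = {"pedigree": _digest(ped_path), "phenotypes": _digest(pheno_path)}
    pedigree = read_pedigree(ped_path)
    pheno = pd.read_csv(
        pheno_path,
        dtype={"tree": str, "site": str, "replicate": str, "set": str},
        keep_default_na=False,
        na_values=[""],
    )
    pheno["provenance"] = pheno["provenance"].fillna("")
    if "control" in pheno.columns:
        pheno["control"] = pheno["control"].fillna("")
    tables = {s: g.reset_index(drop=True) for s, g in pheno.groupby("site")}
    site_filter = config.get("sites")
    if site_filter:
        tables = {s: t for s, t in tables.items() if s in site_filter}

    traits = config["traits"]
    ordinal = config.get("ordinal_traits", [])
    binary = config.get("binary_traits", [])
    variants = tuple(config.get("variants", ("ablup_f", "ablup_r", "ablup_gc1", "ablup_gc2")))

    uni = run_univariate_suite(
        pedigree, tables, traits, variants, ordinal, binary, manifest,
        compute_pev=config.get("compute_pev", True),
    )
    uni.to_csv(os.path.join(out_dir, "univariate_parameters.csv"), index=False)
    for site, sub in uni.groupby("site"):
        sub.to_csv(
            os.path.join(out_dir, f"univariate_parameters_{site}.csv"), index=False
        )

    if config.get("correlations", True) and len(traits) >= 2:
        cvariants = tuple(config.get("correlation_variants", ("ablup_f", "ablup_gc1")))
        res = run_correlation_suite(
            pedigree, tables, traits, cvariants, ordinal,
            cross_site=config.get("cross_site", True),
            mantel_permutations=config.get("mantel_permutations", 999),
            seed=seed, manifest=manifest,
        )
        for key in ("pairs", "cross_site", "mantel", "modules"):
            res[key].to_csv(os.path.join(out_dir, f"correlation_{key}.csv"), index=False)
    manifest.write(os.path.join(out_dir, "manifest.json"))
    return manifest
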