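"""Synthetic provenance/progeny trials.

Generates open-pollinated (OP) family trials with the statistical
structure the animal-model analysis assumes: provenances with their own
genetic means (optionally a deterministic cline in latitude of origin),
mothers nested in provenances, OP offspring planted in a
replicate/set-within-replicate layout together with clonally repeated
control lots, and traits that may be continuous, ordinal (thresholded
latent) or binary.

Pollination comes in two flavours:

``local``
    each offspring's pollen parent is an independent draw from its own
    provenance (mean = provenance effect), the biology under which a
    provenance term — fixed, random or as a two-sided contemporary group —
    is correctly specified;
``global``
    pollen parents come from a single site-wide pool with mean
    ``delta_pollen`` and variance ``pollen_pool_var``, the long-distance
    pollen-flow biology that motivates a separate phantom paternal group.

Truth (every individual's breeding value, provenance effects, generating
parameters) is returned alongside each trial for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pedigree import PedigreeRecord, read_pedigree


@dataclass(frozen=True)
class TraitDef:
    """One simulated trait: measurement scale and discretisation."""

    name: str = "y"
    kind: str = "continuous"  # continuous | ordinal | binary
    n_classes: int = 9
    prevalence: float = 0.5

    def __post_init__(self):
        if self.kind not in ("continuous", "ordinal", "binary"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "ordinal" and self.n_classes < 2:
            raise ValueError("ordinal traits need at least 2 classes")
        if self.kind == "binary" and not 0 < self.prevalence < 1:
            raise ValueError("binary prevalence must be in (0, 1)")


@dataclass
class SimulationConfig:
    """Generating parameters of a provenance/progeny trial.

    The defaults emulate the motivating Douglas-fir trial series: 30
    replicates of 7 sets, 238 OP families (34 per set) plus 2 control
    lots, provenances sampled between 36 and 48 degrees N, and variance
    components matching the flagship growth trait of that series
    (sigma2_p = 140, sigma2_g = 212, sigma2_rep = 45, sigma2_set = 15,
    sigma2_e = 671; the provenance count itself is not published — 14
    gives the equal per-set provenance representation of the design).
    """

    n_provenances: int = 14
    mothers_per_provenance: int = 17
    offspring_per_mother: int = 30
    replicates: int = 30
    sets_per_replicate: int = 7
    n_controls: int = 2
    latitudes: tuple | None = None  # per-provenance latitude of origin, deg N
    sigma2_p: float = 140.0
    sigma2_g: float = 212.0
    sigma2_rep: float = 45.0
    sigma2_set: float = 15.0
    sigma2_e: float = 671.0
    cline_slope: float = 0.0  # provenance-mean change per degree latitude
    pollen: str = "local"  # local | global
    delta_pollen: float = 0.0  # pollen-pool mean shift (global mode)
    pollen_pool_var: float | None = None  # defaults to sigma2_g
    n_sites: int = 1
    cross_site_rg: float = 1.0
    traits: tuple = (TraitDef(),)
    trait_genetic_corr: tuple | None = None  # (T x T) genetic correlation
    seed: int = 0

    def __post_init__(self):
        if self.offspring_per_mother < 1:
            raise ValueError("offspring_per_mother must be >= 1")
        for v in (self.sigma2_p, self.sigma2_g, self.sigma2_rep, self.sigma2_set, self.sigma2_e):
            if v < 0:
                raise ValueError("variances must be non-negative")
        if self.pollen not in ("local", "global"):
            raise ValueError("pollen must be 'local' or 'global'")
        if abs(self.cross_site_rg) > 1:
            raise ValueError("|cross-site genetic correlation| must be <= 1")
        if isinstance(self.traits, TraitDef):
            self.traits = (self.traits,)
        self.traits = tuple(self.traits)

    @classmethod
    def from_targets(cls, h2: float, qst: float, **kwargs) -> "SimulationConfig":
        """Config on a unit phenotypic scale hitting nominal h2 and Q_ST.

        Sets sigma2_g = h2, sigma2_e = 1 - h2 (so sigma2_g + sigma2_e = 1)
        and sigma2_p = qst / (1 - qst) * 2 sigma2_g, with small block
        variances (rep 0.05, set 0.02).
        """
        s2g = h2
        s2e = 1.0 - h2
        s2p = qst / (1.0 - qst) * 2.0 * s2g
        defaults = dict(
            sigma2_g=s2g, sigma2_e=s2e, sigma2_p=s2p, sigma2_rep=0.05, sigma2_set=0.02
        )
        defaults.update(kwargs)
        return cls(**defaults)

    @property
    def provenance_latitudes(self) -> np.ndarray:
        if self.latitudes is not None:
            lat = np.asarray(self.latitudes, dtype=float)
            if len(lat) != self.n_provenances:
                raise ValueError("latitudes must have one entry per provenance")
            return lat
        return np.linspace(36.0, 48.0, self.n_provenances)

    @property
    def qst_nominal(self) -> float:
        den = self.sigma2_p + 2.0 * self.sigma2_g
        return self.sigma2_p / den if den > 0 else 0.0

    @property
    def h2_nominal(self) -> float:
        den = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / den if den > 0 else 0.0


@dataclass
class SyntheticTruth:
    """Ground truth stored with every generated trial."""

    config: SimulationConfig
    breeding_values: pd.DataFrame  # individual x (site, trait) true additive values
    provenance_effects: pd.DataFrame  # provenance x (site, trait)
    latitudes: pd.Series  # per provenance


def _trait_chol(cfg: SimulationConfig) -> np.ndarray:
    T = len(cfg.traits)
    if cfg.trait_genetic_corr is None:
        R = np.eye(T)
    else:
        R = np.asarray(cfg.trait_genetic_corr, dtype=float)
        if R.shape != (T, T):
            raise ValueError("trait_genetic_corr must be T x T")
    return np.linalg.cholesky(R + 1e-12 * np.eye(T))


def _site_chol(cfg: SimulationConfig) -> np.ndarray:
    S = cfg.n_sites
    R = np.full((S, S), cfg.cross_site_rg)
    np.fill_diagonal(R, 1.0)
    return np.linalg.cholesky(R + 1e-12 * np.eye(S))


def _mvn_site_trait(rng, n, cfg, var, site_chol, trait_chol, mean=0.0):
    """Draw n iid (site x trait) matrices with kron(site, trait) correlation."""
    z = rng.standard_normal((n, cfg.n_sites, len(cfg.traits)))
    out = np.einsum("su,nuv,tv->nst", site_chol, z, trait_chol)
    return mean + np.sqrt(var) * out


def simulate_trial(config: SimulationConfig, seed: int | None = None):
    """Generate one trial: (pedigree records, phenotype table, truth).

    The phenotype table has columns ``tree, site, replicate, set,
    provenance, control`` plus one column per trait.  All randomness comes
    from ``seed`` (default ``config.seed``).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    T = len(cfg.traits)
    S = cfg.n_sites
    Lt = _trait_chol(cfg)
    Ls = _site_chol(cfg)
    lat = cfg.provenance_latitudes
    provs = [f"P{i+1:02d}" for i in range(cfg.n_provenances)]
    sites = [f"SITE{s+1}" for s in range(S)]

    # provenance effects: deterministic cline + independent draw per site/trait
    cline = cfg.cline_slope * (lat - lat.mean())
    prov_eff = rng.standard_normal((cfg.n_provenances, S, T)) * np.sqrt(cfg.sigma2_p)
    prov_eff += cline[:, None, None]

    pedigree = []
    bv = {}
    mother_ids = {}
    for ip, p in enumerate(provs):
        for m in range(cfg.mothers_per_provenance):
            mid = f"{p}_M{m+1:03d}"
            mother_ids.setdefault(p, []).append(mid)
            pedigree.append(PedigreeRecord(mid, provenance=p))
    n_mothers = len(pedigree)
    mdev = _mvn_site_trait(rng, n_mothers, cfg, cfg.sigma2_g, Ls, Lt)
    for k, rec in enumerate(pedigree):
        ip = provs.index(rec.provenance)
        bv[rec.individual] = prov_eff[ip] + mdev[k]

    controls = [f"CTRL{c+1}" for c in range(cfg.n_controls)]
    cdev = _mvn_site_trait(rng, cfg.n_controls, cfg, cfg.sigma2_g, Ls, Lt)
    for c, cid in enumerate(controls):
        pedigree.append(PedigreeRecord(cid))
        bv[cid] = cdev[c]

    pool_var = cfg.sigma2_g if cfg.pollen_pool_var is None else cfg.pollen_pool_var
    n_sets = cfg.sets_per_replicate
    rows = []
    off_records = []
    fam_counter = 0
    n_off = cfg.offspring_per_mother
    rep_slots = (np.arange(n_off) * cfg.replicates) // n_off
    for ip, p in enumerate(provs):
        for mid in mother_ids[p]:
            set_id = fam_counter % n_sets
            fam_counter += 1
            # offspring split evenly across sites, spread over replicates
            site_of = np.arange(n_off) % S
            fdev = _mvn_site_trait(rng, n_off, cfg, pool_var, Ls, Lt)
            if cfg.pollen == "local":
                fbv = prov_eff[ip][None, :, :] + fdev
            else:
                fbv = cfg.delta_pollen + fdev
            mend = _mvn_site_trait(rng, n_off, cfg, cfg.sigma2_g / 2.0, Ls, Lt)
            for j in range(n_off):
                oid = f"{mid}_O{j+1:02d}"
                off_records.append(PedigreeRecord(oid, dam=mid, provenance=p))
                bv[oid] = 0.5 * bv[mid] + 0.5 * fbv[j] + mend[j]
                rows.append(
                    dict(
                        tree=oid,
                        site=sites[site_of[j]],
                        replicate=f"R{rep_slots[j]+1:02d}",
                        set=f"S{set_id+1}",
                        provenance=p,
                        control="",
                    )
                )
    pedigree.extend(off_records)

    # controls: one tree per (site, replicate, set)
    for cid in controls:
        for s in range(S):
            for r in range(cfg.replicates):
                for st in range(n_sets):
                    rows.append(
                        dict(
                            tree=cid,
                            site=sites[s],
                            replicate=f"R{r+1:02d}",
                            set=f"S{st+1}",
                            provenance="",
                            control=cid,
                        )
                    )

    pheno = pd.DataFrame(rows)
    # block and residual effects, then the latent trait values
    rep_eff = {
        (s, r, t): v
        for (s, r, t), v in np.ndenumerate(
            rng.standard_normal((S, cfg.replicates, T)) * np.sqrt(cfg.sigma2_rep)
        )
    }
    set_eff = {
        (s, r, st, t): v
        for (s, r, st, t), v in np.ndenumerate(
            rng.standard_normal((S, cfg.replicates, n_sets, T))
            * np.sqrt(cfg.sigma2_set)
        )
    }
    site_idx = pheno["site"].map({nm: k for k, nm in enumerate(sites)}).to_numpy()
    rep_idx = pheno["replicate"].str.slice(1).astype(int).to_numpy() - 1
    set_idx = pheno["set"].str.slice(1).astype(int).to_numpy() - 1
    latent = np.empty((len(pheno), T))
    a_mat = np.stack([bv[t] for t in pheno["tree"]])  # (n, S, T)
    for t in range(T):
        a = a_mat[np.arange(len(pheno)), site_idx, t]
        r = np.array([rep_eff[(s, rr, t)] for s, rr in zip(site_idx, rep_idx)])
        st = np.array(
            [set_eff[(s, rr, ss, t)] for s, rr, ss in zip(site_idx, rep_idx, set_idx)]
        )
        e = rng.standard_normal(len(pheno)) * np.sqrt(cfg.sigma2_e)
        latent[:, t] = a + r + st + e

    for t, td in enumerate(cfg.traits):
        col = latent[:, t]
        if td.kind == "continuous":
            pheno[td.name] = col
        elif td.kind == "ordinal":
            qs = np.quantile(col, np.linspace(0, 1, td.n_classes + 1)[1:-1])
            pheno[td.name] = 1 + np.searchsorted(qs, col).astype(float)
        else:  # binary
            thr = np.quantile(col, 1.0 - td.prevalence)
            pheno[td.name] = (col > thr).astype(float)

    trait_names = [td.name for td in cfg.traits]
    ids = [r.individual for r in pedigree]
    bv_df = pd.DataFrame(
        {
            (sites[s], trait_names[t]): [bv[i][s, t] for i in ids]
            for s in range(S)
            for t in range(T)
        },
        index=ids,
    )
    bv_df.columns = pd.MultiIndex.from_tuples(bv_df.columns, names=["site", "trait"])
    pe_df = pd.DataFrame(
        {
            (sites[s], trait_names[t]): prov_eff[:, s, t]
            for s in range(S)
            for t in range(T)
        },
        index=provs,
    )
    pe_df.columns = pd.MultiIndex.from_tuples(pe_df.columns, names=["site", "trait"])
    truth = SyntheticTruth(
        config=cfg,
        breeding_values=bv_df,
        provenance_effects=pe_df,
        latitudes=pd.Series(lat, index=provs),
    )
    return pedigree, pheno, truth


def export_trial(trial, outdir) -> dict:
    """Write a generated trial to ``outdir`` as delimited text.

    ``trial`` is the (pedigree, phenotypes, truth) tuple from
    :func:`simulate_trial`.  Writes ``pedigree.csv``, ``phenotypes.csv``,
    ``truth_breeding_values.csv`` and ``truth_params.json``; returns the
    path map.  Fixed seeds give byte-identical files.
    """
    import os

    pedigree, pheno, truth = trial
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "pedigree": os.path.join(outdir, "pedigree.csv"),
        "phenotypes": os.path.join(outdir, "phenotypes.csv"),
        "truth_bv": os.path.join(outdir, "truth_breeding_values.csv"),
        "truth_params": os.path.join(outdir, "truth_params.json"),
    }
    with open(paths["pedigree"], "w", encoding="utf-8") as fh:
        fh.write("individual,dam,sire,provenance\n")
        for r in pedigree:
            fh.write(f"{r.individual},{r.dam},{r.sire},{r.provenance}\n")
    pheno.to_csv(paths["phenotypes"], index=False)
    flat = truth.breeding_values.copy()
    flat.columns = [f"{s}:{t}" for s, t in flat.columns]
    flat.index.name = "individual"
    flat.to_csv(paths["truth_bv"])
    cfg = asdict(truth.config)
    cfg["traits"] = [asdict(td) for td in truth.config.traits]
    with open(paths["truth_params"], "w", encoding="utf-8") as fh:
        json.dump(cfg, fh, indent=1, sort_keys=True, default=float)
    return paths


def load_trial(outdir):
    """Read back an exported trial (pedigree records and phenotype table)."""
    import os

    pedigree = read_pedigree(os.path.join(outdir, "pedigree.csv"))
    pheno = pd.read_csv(
        os.path.join(outdir, "phenotypes.csv"),
        dtype={"tree": str, "site": str, "replicate": str, "set": str},
        keep_default_na=False,
        na_values=[""],
    )
    pheno["provenance"] = pheno["provenance"].fillna("")
    pheno["control"] = pheno.get("control", pd.Series("", index=pheno.index)).fillna("")
    return pedigree, pheno
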