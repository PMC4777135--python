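"""Comparison reports: rank persistence, SEP scatter data, pipeline runs.

The report layer only rearranges quantities already computed by fits or
cross-validation; it never re-estimates anything.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kernels import (
    RelationshipKernel,
    build_additive_kernel,
    build_dominance_kernel,
    build_numerator_relationship,
    compute_allele_frequencies,
    hadamard,
    relationship_summaries,
)
from .crossval import consistency_matrix, cross_validate, make_folds
from .io import (
    dump_config,
    read_genotypes_tsv,
    read_pedigree_csv,
    read_phenotypes_csv,
    write_genotypes_tsv,
    write_pedigree_csv,
    write_phenotypes_csv,
)
from .kernels import PedigreeTable
from .remlfit import (
    FitOptions,
    REMLFit,
    aic,
    heritability,
    model_ladder,
    sampling_correlation_diagnostic,
    variance_proportions,
)
from .simdata import SimulationConfig, config_to_dict, simulate_dataset

__all__ = [
    "rank_comparison",
    "sep_comparison",
    "PipelineConfig",
    "run_pipeline",
]


def rank_comparison(
    ebv_a: pd.Series, ebv_b: pd.Series, top_k: int = 50
) -> tuple[int, pd.DataFrame]:
    """Persistence of top-ranked individuals between two EBV sets.

    Individuals are ranked by descending EBV, ties broken by ascending
    id.  Returns the size of the intersection of the two top-k sets and
    a rank table over their union.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    ids = ebv_a.index.intersection(ebv_b.index)
    if len(ids) == 0:
        raise ValueError("EBV series share no individuals")
    if top_k > len(ids):
        raise ValueError(f"top_k={top_k} exceeds the {len(ids)} shared individuals")

    def ranks(s: pd.Series) -> pd.Series:
        frame = s.loc[ids].rename("ebv").to_frame()
        frame["_id"] = frame.index.astype(str)
        frame = frame.sort_values(["ebv", "_id"], ascending=[False, True])
        return pd.Series(np.arange(1, len(frame) + 1), index=frame.index)

    ra, rb = ranks(ebv_a), ranks(ebv_b)
    top_a = set(ra[ra <= top_k].index)
    top_b = set(rb[rb <= top_k].index)
    union = sorted(top_a | top_b, key=str)
    table = pd.DataFrame(
        {"id": union, "rank_a": ra.loc[union].values, "rank_b": rb.loc[union].values}
    )
    return len(top_a & top_b), table


def sep_comparison(
    fit_a: REMLFit, fit_b: REMLFit, ids: pd.Index | None = None
) -> tuple[pd.DataFrame, float]:
    """Paired SEPs of additive BLUPs and the share improved under B.

    Returns the paired table and the fraction of individuals whose SEP
    under ``fit_b`` is strictly smaller than under ``fit_a`` (points
    below the 45-degree line in the usual scatter).  With ``ids`` the
    comparison is restricted to those individuals (e.g. the phenotyped
    progeny when one fit also carries pedigree founders); otherwise the
    two fits must cover identical individuals.
    """
    sa, sb = fit_a.sep, fit_b.sep
    if ids is not None:
        sa, sb = sa.loc[sa.index.intersection(ids)], sb.loc[sb.index.intersection(ids)]
    if set(sa.index) != set(sb.index):
        raise ValueError("fits cover different individuals")
    table = pd.DataFrame(
        {"id": sa.index, "sep_a": sa.values, "sep_b": sb.loc[sa.index].values}
    )
    frac = float((table["sep_b"] < table["sep_a"]).mean())
    return table, frac


# ---------------------------------------------------------------------------
# pipeline orchestration

@dataclass
class PipelineConfig:
    """End-to-end run description: inputs (or simulation), models, CV."""

    out_dir: str
    seed: int = 0
    simulation: dict | None = None  # SimulationConfig kwargs
    genotypes: str | None = None  # path alternatives to simulation
    phenotypes: str | None = None
    pedigree: str | None = None
    traits: list[dict] = field(default_factory=list)  # {name, transform}
    models: list[str] = field(
        default_factory=lambda: ["ABLUP", "GBLUP-A", "GBLUP-AD", "GBLUP-ADE", "GBLUP-AE"]
    )
    dominance_parameterization: str = "classical"
    stabilize_epsilon: float = 0.0
    cv: dict = field(
        default_factory=lambda: {
            "enabled": True,
            "schemes": ["random", "block", "family"],
            "k": 10,
            "reps": 5,
            "block_mode": "average",
            "models": None,  # default: same as pipeline models
        }
    )
    write_kernels: bool = False
    top_k: int = 50

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        cfg = dict(cfg)
        if "out_dir" not in cfg:
            raise ValueError("pipeline config needs out_dir")
        if cfg.get("simulation") is None and (
            cfg.get("genotypes") is None or cfg.get("phenotypes") is None
        ):
            raise ValueError(
                "pipeline config needs either a simulation block or "
                "genotypes+phenotypes paths"
            )
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys {sorted(unknown)}")
        base = cls(out_dir=cfg.pop("out_dir"))
        for k, v in cfg.items():
            if k == "cv" and isinstance(v, dict):
                base.cv.update(v)
            else:
                setattr(base, k, v)
        return base


def _fit_report(fit_: REMLFit, out: Path, name: str) -> dict:
    props = variance_proportions(fit_)
    comp = pd.DataFrame(
        {
            "term": list(fit_.estimates),
            "estimate": [fit_.estimates[t] for t in fit_.estimates],
            "se": [fit_.se[t] for t in fit_.estimates],
            "percent": [props[t] for t in fit_.estimates],
        }
    )
    comp.to_csv(out / f"varcomp_{name}.csv", index=False, float_format="%.10g")
    h2, h2_se = heritability(fit_)
    pd.DataFrame({"h2": [h2], "se": [h2_se]}).to_csv(
        out / f"h2_{name}.csv", index=False, float_format="%.10g"
    )
    ebv = fit_.blups["additive"]
    ebv.rename(columns={"blup": "ebv"}).to_csv(
        out / f"ebv_{name}.csv", float_format="%.10g"
    )
    diag: dict = {
        "model": name,
        "loglik": fit_.loglik,
        "aic": aic(fit_),
        "converged": fit_.converged,
        "n_iter": fit_.n_iter,
        "pinned": sorted(fit_.pinned),
        "h2": h2,
        "h2_se": h2_se,
    }
    try:
        eig = sampling_correlation_diagnostic(fit_)
        diag["eigenvalues"] = [float(v) for v in eig.eigenvalues]
        diag["cumulative_proportion"] = [float(v) for v in eig.cumulative_proportion]
    except Exception as err:  # boundary-only fits
        diag["eigen_diagnostic_error"] = str(err)
    with open(out / f"diagnostics_{name}.json", "w") as fh:
        json.dump(diag, fh, indent=1, sort_keys=True)
    return diag


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate or load data, build kernels, fit the ladder, cross-validate.

    Writes a reproducible bundle of CSV/JSON artifacts plus a manifest,
    and returns the manifest dictionary.  Any stage failure aborts with
    the stage name; artifacts of completed stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "opgblup",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": [],
        "models": [],
        "cv_schemes": [],
    }
    t0 = time.time()
    stage = "setup"
    try:
        stage = "data"
        if config.simulation is not None:
            sim_cfg = SimulationConfig(**{**config.simulation, "seed": config.seed})
            data = simulate_dataset(sim_cfg)
            genotypes, phen = data.genotypes, data.phenotypes
            ped = PedigreeTable.from_frame(data.assumed_pedigree)
            write_genotypes_tsv(genotypes, out / "genotypes.tsv")
            write_phenotypes_csv(phen, out / "phenotypes.csv")
            write_pedigree_csv(data.assumed_pedigree, out / "pedigree_assumed.csv")
            write_pedigree_csv(data.truth.true_pedigree, out / "pedigree_true.csv")
            dump_config(config_to_dict(sim_cfg), out / "simulation_config.yaml")
            traits = config.traits or [{"name": sim_cfg.trait_name, "transform": "none"}]
        else:
            genotypes = read_genotypes_tsv(config.genotypes)
            phen = read_phenotypes_csv(config.phenotypes)
            if config.pedigree is None:
                raise ValueError("pedigree path required for the ABLUP model")
            ped = read_pedigree_csv(config.pedigree)
            traits = config.traits
            if not traits:
                raise ValueError("traits must be listed for file-based runs")
        manifest["stages"].append("data")

        stage = "kernels"
        freqs, _ = compute_allele_frequencies(genotypes)
        G_add = build_additive_kernel(genotypes, freqs)
        G_dom = build_dominance_kernel(
            genotypes, freqs, config.dominance_parameterization
        )
        if config.stabilize_epsilon > 0:
            from .kernels import stabilize

            G_add = stabilize(G_add, config.stabilize_epsilon)
            G_dom = stabilize(G_dom, config.stabilize_epsilon)
        kernels = {
            "A": build_numerator_relationship(ped),
            "G_add": G_add,
            "G_dom": G_dom,
            "AxA": hadamard(G_add, G_add),
            "DxD": hadamard(G_dom, G_dom),
            "AxD": hadamard(G_add, G_dom),
        }
        if config.write_kernels:
            from .io import write_kernel_tsv

            for name, k in kernels.items():
                write_kernel_tsv(k, out / f"kernel_{name}.tsv")
        fam_map = dict(zip(phen["id"].astype(str), phen["family"].astype(str)))
        summary = relationship_summaries(
            RelationshipKernel(
                "G_add",
                phen["id"].astype(str).tolist(),
                kernels["G_add"].align(phen["id"].astype(str).tolist()),
            ),
            fam_map,
        )
        summary.within.to_csv(out / "relationship_summary.csv", index=False)
        summary.histogram.to_csv(out / "relationship_histogram.csv", index=False)
        manifest["stages"].append("kernels")

        stage = "models"
        fits_by_trait: dict[str, dict[str, REMLFit]] = {}
        for tr in traits:
            tname, transform = tr["name"], tr.get("transform", "none")
            fits = model_ladder(phen, tname, kernels, transform, config.models)
            fits_by_trait[tname] = fits
            for mname, fit_ in fits.items():
                _fit_report(fit_, out, f"{tname}_{mname}")
            manifest["models"] = list(fits)
            # comparison reports against the pedigree model where present
            if "ABLUP" in fits:
                for other in fits:
                    if other == "ABLUP":
                        continue
                    ids = fits["ABLUP"].ebv.index.intersection(fits[other].ebv.index)
                    overlap, table = rank_comparison(
                        fits["ABLUP"].ebv.loc[ids],
                        fits[other].ebv.loc[ids],
                        min(config.top_k, len(ids)),
                    )
                    table.to_csv(
                        out / f"rank_{tname}_ABLUP_vs_{other}.csv", index=False
                    )
                    sep_table, frac = sep_comparison(
                        fits["ABLUP"], fits[other], ids
                    )
                    sep_table.to_csv(
                        out / f"sep_{tname}_ABLUP_vs_{other}.csv",
                        index=False,
                        float_format="%.10g",
                    )
        manifest["stages"].append("models")

        stage = "cross-validation"
        if config.cv.get("enabled", True):
            cv_models = config.cv.get("models") or config.models
            blk_map = dict(zip(phen["id"].astype(str), phen["block"].astype(str)))
            ids = phen["id"].astype(str).tolist()
            for tr in traits:
                tname, transform = tr["name"], tr.get("transform", "none")
                ebvs = {
                    m: fits_by_trait[tname][m].ebv.loc[
                        fits_by_trait[tname][m].ebv.index.intersection(ids)
                    ]
                    for m in cv_models
                }
                for scheme in config.cv.get("schemes", []):
                    plan = make_folds(
                        ids,
                        fam_map,
                        blk_map,
                        scheme,
                        k=config.cv.get("k", 10),
                        reps=config.cv.get("reps", 5),
                        seed=config.seed,
                        block_mode=config.cv.get("block_mode", "average"),
                    )
                    pbvs = {}
                    for m in cv_models:
                        tbl = cross_validate(plan, m, phen, tname, kernels, transform)
                        tbl.to_csv(
                            out / f"pbv_{tname}_{scheme}_{m}.csv",
                            index=False,
                            float_format="%.10g",
                        )
                        pbvs[m] = tbl
                    cons = consistency_matrix(ebvs, pbvs, scheme)
                    cons.to_csv(
                        out / f"consistency_{tname}_{scheme}.csv",
                        float_format="%.10g",
                    )
                    if scheme not in manifest["cv_schemes"]:
                        manifest["cv_schemes"].append(scheme)
        manifest["stages"].append("cross-validation")
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        manifest["wall_seconds"] = time.time() - t0
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest["wall_seconds"] = time.time() - t0
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
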