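"""End-to-end analysis driver.

Runs the full sequence on a sightings + attributes dataset: focal-male
filtering, association indices, associate ranks, feature construction, the
logistic model suite with AIC selection, Monte-Carlo randomization tests of
the associate effects, the top-2 directed network, Girvan-Newman communities
with a modularity null, cluster composition tests, and the directed ERGM.
Every output plus a run manifest (configuration, seeds, package versions)
is written to the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import association as assoc
from . import community as comm
from . import ergm as ergm_mod
from .logistic import MODEL_SUITE, compare_aic, run_model_suite
from .randomization import associate_pool_null, shuffle_predictors_null

log = logging.getLogger("raidnet")

__all__ = ["PipelineConfig", "run_pipeline"]

#: the Table-3-style ERGM statistic set for the closest-associate network
DEFAULT_ERGM_STATS = (
    "arc",
    "AT_T",
    "reciprocity",
    "AinAoutS",
    "OneInAoutS",
    "AinOneOutS",
    "source",
    "AinS",
    "match:raider",
    "abs_diff:age_years",
    "reciprocal_match:raider",
)


@dataclass
class PipelineConfig:
    """Knobs of the end-to-end run; every stochastic stage derives its seed
    from ``seed`` by a fixed offset so reruns are bit-for-bit reproducible."""

    min_sightings: int = 15
    top_k: int = 2
    n_reps: int = 1000
    seed: int = 0
    ergm_lambda: float = 2.0
    ergm_stats: tuple = DEFAULT_ERGM_STATS
    ergm_phase3_samples: int = 1000
    run_ergm: bool = True
    run_modularity_null: bool = True
    modularity_null_reps: int = 200


def _versions() -> dict:
    import networkx
    import numpy
    import pandas
    import scipy

    from . import __version__

    return {
        "raidnet": __version__,
        "python": sys.version.split()[0],
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "networkx": networkx.__version__,
    }


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="list")
    return str(x)


def run_pipeline(
    sightings: pd.DataFrame,
    attributes: pd.DataFrame,
    config: PipelineConfig | None = None,
    outdir=None,
) -> dict:
    """Run the full analysis; returns a results dict and writes artifacts.

    Stages and their outputs (when ``outdir`` is given):
    ai_matrix.csv, ranks.csv, edges.tsv, network.graphml, features.csv,
    models.json, randomization.json, partition.csv, communities.json,
    ergm.json, manifest.json.
    """
    config = config or PipelineConfig()
    results: dict = {"config": asdict(config)}
    artifacts: dict = {}
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    log.info("stage 1/7: association matrix and focal-male filter")
    matrix_all = assoc.build_association_matrix(sightings, attributes)
    focal = assoc.filter_focal_males(
        matrix_all, min_sightings=config.min_sightings, top_m=config.top_k
    )
    results["n_focal"] = len(focal)
    matrix = matrix_all.subset(focal)
    attributes = attributes[attributes["male_id"].isin(focal)].reset_index(drop=True)

    log.info("stage 2/7: ranks, top-%d network, features", config.top_k)
    ranks = assoc.rank_associates(matrix)
    network = assoc.build_top_k_network(
        ranks, matrix, k=config.top_k, attributes=attributes
    )
    features = assoc.make_features(ranks, attributes, k=5)
    results["network_density"] = nx.density(network)

    log.info("stage 3/7: logistic model suite")
    fits = run_model_suite(features)
    aic_table = compare_aic(fits)
    results["models"] = {
        name: {
            "coefficients": dict(zip(f.names, f.params)),
            "se": dict(zip(f.names, f.se)),
            "odds_ratios": dict(zip(f.names, f.odds_ratios)),
            "wald": f.summary().to_dict(orient="index"),
            "aic": f.aic,
            "loglik": f.loglik,
            "converged": f.converged,
            "separated": f.separated,
        }
        for name, f in fits.items()
    }
    results["aic_ranking"] = aic_table.to_dict(orient="index")

    log.info("stage 4/7: randomization tests (%d reps each)", config.n_reps)
    rand: dict = {}
    for r in range(1, 6):
        ens = associate_pool_null(
            features,
            attributes,
            terms=[f"status_{r}"],
            ranks_to_randomize=(r,),
            n_reps=config.n_reps,
            seed=config.seed + 100 + r,
        )
        rand[f"status_{r}"] = ens.summary().to_dict(orient="index")
    ens5 = associate_pool_null(
        features,
        attributes,
        terms=["status_1", "status_2"],
        ranks_to_randomize=(1, 2),
        n_reps=config.n_reps,
        seed=config.seed + 106,
    )
    rand["status_1_2"] = ens5.summary().to_dict(orient="index")
    ens6 = associate_pool_null(
        features,
        attributes,
        terms=MODEL_SUITE["M6_full"],
        ranks_to_randomize=(1, 2),
        n_reps=config.n_reps,
        seed=config.seed + 107,
    )
    rand["full_model"] = ens6.summary().to_dict(orient="index")
    ens_shuffle = shuffle_predictors_null(
        features,
        terms=MODEL_SUITE["M6_full"],
        n_reps=config.n_reps,
        seed=config.seed + 108,
    )
    rand["full_model_shuffled_predictors"] = ens_shuffle.summary().to_dict(orient="index")
    results["randomization"] = rand

    log.info("stage 5/7: Girvan-Newman communities")
    partition = comm.girvan_newman(network)
    results["modularity"] = partition.q
    results["n_clusters"] = partition.n_clusters
    if config.run_modularity_null:
        null = comm.modularity_null(
            network, n_reps=config.modularity_null_reps, seed=config.seed + 200
        )
        results["modularity_null"] = {
            "null_mean": null["null_mean"],
            "null_sd": null["null_sd"],
            "p": null["p"],
        }

    log.info("stage 6/7: cluster composition tests")
    attr = attributes.set_index("male_id")
    nodes = sorted(partition.labels, key=str)
    labels = np.array([partition.labels[v] for v in nodes])
    raider = attr.loc[nodes, "raider"].to_numpy(dtype=float)
    ages = attr.loc[nodes, "age_years"].to_numpy(dtype=float)
    prop_test = comm.cluster_composition_test(
        labels, raider, "proportion", n_reps=config.n_reps, seed=config.seed + 201
    )
    age_test = comm.cluster_composition_test(
        labels, ages, "mean", n_reps=config.n_reps, seed=config.seed + 202
    )
    results["composition_raider"] = prop_test.table.to_dict(orient="records")
    results["composition_age"] = age_test.table.to_dict(orient="records")

    if config.run_ergm:
        log.info("stage 7/7: ERGM (Robbins-Monro)")
        spec = ergm_mod.ErgmSpec(stats=tuple(config.ergm_stats), lam=config.ergm_lambda)
        fit = ergm_mod.fit_robbins_monro(
            network,
            spec,
            seed=config.seed + 300,
            phase3_samples=config.ergm_phase3_samples,
            return_graphs=False,
        )
        results["ergm"] = {
            "stats": list(spec.stats),
            "theta": fit.theta.tolist(),
            "se": fit.se.tolist(),
            "t_ratios": fit.tratios.tolist(),
            "p": fit.pvalues.tolist(),
            "converged": fit.converged,
            "n_restarts": fit.n_restarts,
        }

    if out is not None:
        matrix.to_frame().to_csv(out / "ai_matrix.csv")
        artifacts["ai_matrix"] = "ai_matrix.csv"
        ranks.to_frame().to_csv(out / "ranks.csv", index=False)
        artifacts["ranks"] = "ranks.csv"
        with open(out / "edges.tsv", "w") as fh:
            fh.write("src\tdst\n")
            for i, j in sorted(network.edges):
                fh.write(f"{i}\t{j}\n")
        artifacts["edges"] = "edges.tsv"
        gml = network.copy()
        for v in gml.nodes:
            gml.nodes[v]["cluster"] = int(partition.labels[v])
        nx.write_graphml(gml, out / "network.graphml")
        artifacts["network"] = "network.graphml"
        features.to_csv(out / "features.csv", index=False)
        artifacts["features"] = "features.csv"
        partition.to_frame().to_csv(out / "partition.csv", index=False)
        artifacts["partition"] = "partition.csv"
        for key, fname in [
            ("models", "models.json"),
            ("randomization", "randomization.json"),
        ]:
            _dump(results[key], out / fname)
            artifacts[key] = fname
        _dump(
            {
                "modularity": results["modularity"],
                "n_clusters": results["n_clusters"],
                "modularity_null": results.get("modularity_null"),
                "composition_raider": results["composition_raider"],
                "composition_age": results["composition_age"],
            },
            out / "communities.json",
        )
        artifacts["communities"] = "communities.json"
        if "ergm" in results:
            _dump(results["ergm"], out / "ergm.json")
            artifacts["ergm"] = "ergm.json"
        cfg_hash = hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        _dump(
            {
                "config": asdict(config),
                "config_hash": cfg_hash,
                "seed": config.seed,
                "versions": _versions(),
                "artifacts": artifacts,
            },
            out / "manifest.json",
        )
    results["artifacts"] = artifacts
    return results
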