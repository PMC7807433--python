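"""End-to-end orchestration: data in, network artifacts out.

``run_pipeline`` drives every stage — (optionally simulated) input,
global abundance filtering, partitioning, per-partition ensemble
inference, topology summaries, cross-network comparison with core
extraction, compositional diet analysis, and the Procrustes-matched
layout — writing plain-text artifacts plus a manifest with parameters
and output checksums.  Two runs with the same config produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .compare import (
    cluster_networks,
    edge_jaccard,
    intersect_networks,
    shared_edge_counts,
)
from .composition import (
    aitchison_distance,
    aldex_effect,
    clr_transform,
    czm_impute,
    diet_node_summary,
    pca_biplot,
    permanova,
)
from .datatypes import OTUTable, SampleMetadata
from .inference import CoOccurrenceModel
from .io import (
    read_metadata,
    read_otu_table,
    write_metadata,
    write_network,
    write_otu_table,
)
from .layout import match_layout
from .preprocess import PartitionScheme, filter_global_abundance, partition_datasets
from .simulate import SimConfig, generate_community, write_ground_truth

DEFAULTS: dict[str, Any] = {
    "seed": 1,
    "preprocess": {
        "min_frac": 0.00005,
        "scheme": "lake",
        "min_samples": 20,
        "occurrence": 0.31,
        "keep_sum": True,
    },
    "infer": {
        "n_top": 1000,
        "mode": "both",
        "n_perm": 1000,
        "n_boot": 1000,
        "alpha": 0.05,
    },
    "diet": {
        "enabled": True,
        "lake": None,
        "exclude": ["planktivore"],
        "merge": {"scale-eater": "carnivore"},
        "occurrence": 0.60,
        "min_samples": 20,
        "n_mc": 128,
        "n_perm": 999,
    },
    "layout": {"n_seeds": 100},
}


class PipelineError(RuntimeError):
    """Raised with the failing stage's name prefixed."""


def _merge_config(config: dict[str, Any]) -> dict[str, Any]:
    merged = json.loads(json.dumps(DEFAULTS))
    for key, val in config.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _load_inputs(
    cfg: dict[str, Any], out: Path
) -> tuple[OTUTable, SampleMetadata]:
    if "simulate" in cfg:
        sim = cfg["simulate"]
        if sim.get("study_mimic"):
            config = SimConfig.study_mimic(seed=cfg["seed"])
        else:
            from .simulate import GroupSpec, PlantedPair

            groups = [GroupSpec(**g) for g in sim["groups"]]
            pairs = [PlantedPair(**p) for p in sim.get("planted_pairs", [])]
            config = SimConfig(
                n_otus=sim["n_otus"], groups=groups, planted_pairs=pairs,
                seed=cfg["seed"],
            )
        table, meta, truth = generate_community(config)
        write_otu_table(table, out / "otu_table.tsv")
        write_metadata(meta, out / "metadata.tsv")
        write_ground_truth(truth, out / "truth.tsv")
        return table, meta
    if "input" not in cfg:
        raise PipelineError("input: config needs either 'simulate' or 'input'")
    table = read_otu_table(cfg["input"]["otu"])
    meta = read_metadata(cfg["input"]["metadata"])
    return table, meta


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Run every stage; returns the manifest (also written as JSON)."""
    cfg = _merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        table, meta = _load_inputs(cfg, out)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"input: {err}") from err

    pp = cfg["preprocess"]
    try:
        table = filter_global_abundance(table, pp["min_frac"])
        scheme = PartitionScheme(
            mode=pp["scheme"], min_samples=pp["min_samples"]
        )
        partitions = partition_datasets(table, meta, scheme)
    except Exception as err:
        raise PipelineError(f"preprocess: {err}") from err

    inf = cfg["infer"]
    nets = {}
    rows = []
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    try:
        for name, (sub, _) in sorted(partitions.items()):
            model = CoOccurrenceModel.from_otu_table(
                sub,
                min_occurrence_frac=pp["occurrence"],
                keep_sum=pp["keep_sum"],
                n_top=inf["n_top"],
                mode=inf["mode"],
                name=name,
            )
            res = model.fit(
                n_perm=inf["n_perm"], n_boot=inf["n_boot"],
                alpha=inf["alpha"], seed=cfg["seed"],
            )
            nets[name] = res.network
            rows.append(res.summary(seed=cfg["seed"]))
            safe = name.replace(" ", "_")
            write_network(res.network, net_dir / f"{safe}.edge_tsv")
            write_network(res.network, net_dir / f"{safe}.graphml", format="graphml")
    except Exception as err:
        raise PipelineError(f"infer: {err}") from err
    pd.concat(rows, ignore_index=True).to_csv(
        out / "topology.tsv", sep="\t", index=False
    )

    try:
        nonempty = {n: g for n, g in nets.items() if g.n_edges}
        if len(nonempty) >= 2:
            J = edge_jaccard(nonempty)
            J.to_csv(out / "jaccard.tsv", sep="\t")
            Z = cluster_networks(J)
            pd.DataFrame(
                Z, columns=["left", "right", "height", "size"]
            ).to_csv(out / "dendrogram.tsv", sep="\t", index=False)
            if len(nonempty) <= 6:
                regions = shared_edge_counts(nonempty)
                pd.DataFrame(
                    [
                        {"region": "&".join(sorted(k)), "n_edges": v}
                        for k, v in sorted(
                            regions.items(), key=lambda kv: "&".join(sorted(kv[0]))
                        )
                    ]
                ).to_csv(out / "venn.tsv", sep="\t", index=False)
            core = intersect_networks(nonempty)
            write_network(core, out / "core.edge_tsv")
    except Exception as err:
        raise PipelineError(f"compare: {err}") from err

    dcfg = cfg["diet"]
    manifest_diet: dict[str, Any] = {}
    if dcfg.get("enabled"):
        try:
            manifest_diet = _diet_stage(table, meta, nets, cfg, out)
        except Exception as err:
            raise PipelineError(f"diet: {err}") from err

    manifest = {
        "version": __version__,
        "config": cfg,
        "diet": manifest_diet,
        "outputs": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _diet_stage(
    table: OTUTable,
    meta: SampleMetadata,
    nets: dict,
    cfg: dict[str, Any],
    out: Path,
) -> dict[str, Any]:
    dcfg = cfg["diet"]
    meta = meta.merge_diets(dcfg.get("merge", {}))
    lake = dcfg.get("lake")
    if lake is None:
        with_diet = meta.frame[meta.frame["diet"] != ""]
        if with_diet.empty:
            return {"skipped": "no diet labels"}
        lake = with_diet["lake"].value_counts().idxmax()
    sub_meta = meta.frame[
        (meta.frame["lake"] == lake) & (meta.frame["diet"] != "")
    ]
    sub_meta = sub_meta[~sub_meta["diet"].isin(dcfg.get("exclude", []))]
    if sub_meta.empty:
        return {"skipped": f"no usable diet samples in {lake!r}"}
    samples = list(sub_meta.index)
    sub = table.select_samples(samples)
    sub = sub.select_otus(sub.counts.sum(axis=1) > 0)
    ddir = out / "diet"
    ddir.mkdir(exist_ok=True)

    # per-diet networks (copresence only, stricter occurrence filter)
    scheme = PartitionScheme(
        mode="diet", min_samples=dcfg["min_samples"], lake=lake
    )
    diet_parts = partition_datasets(table, meta, scheme)
    inf = cfg["infer"]
    diet_nets = {}
    for diet, (dtab, _) in sorted(diet_parts.items()):
        if diet in dcfg.get("exclude", []):
            continue
        model = CoOccurrenceModel.from_otu_table(
            dtab, min_occurrence_frac=dcfg["occurrence"], keep_sum=True,
            n_top=inf["n_top"], mode="copresence_only", name=f"{lake}:{diet}",
        )
        res = model.fit(
            n_perm=inf["n_perm"], n_boot=inf["n_boot"],
            alpha=inf["alpha"], seed=cfg["seed"],
        )
        diet_nets[diet] = res.network
        write_network(res.network, ddir / f"net_{diet}.edge_tsv")

    # compositional mapping on the whole-lake network
    comp = czm_impute(sub.counts.T)
    clr = pd.DataFrame(
        clr_transform(comp), index=samples, columns=sub.otu_ids
    )
    pca = pca_biplot(clr)
    pca.sample_scores.iloc[:, :10].to_csv(ddir / "pca_samples.tsv", sep="\t")
    pca.otu_loadings.iloc[:, :10].to_csv(ddir / "pca_otus.tsv", sep="\t")

    diets = sub_meta["diet"]
    species = sub_meta["species"]
    perma = permanova(
        aitchison_distance(clr), diets.values, species.values,
        n_perm=dcfg["n_perm"], seed=cfg["seed"], pairwise=True,
    )
    perma.table.to_csv(ddir / "permanova.tsv", sep="\t")
    if perma.pairwise is not None:
        perma.pairwise.to_csv(ddir / "permanova_pairwise.tsv", sep="\t", index=False)

    levels = sorted(set(diets))
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            la, lb = levels[i], levels[j]
            eff = aldex_effect(
                sub.counts.T, diets.values, levels=(la, lb),
                n_mc=dcfg["n_mc"], seed=cfg["seed"], otu_ids=sub.otu_ids,
            )
            eff.to_csv(ddir / f"effects_{la}_vs_{lb}.tsv", sep="\t")

    result: dict[str, Any] = {"lake": lake, "permanova_p": perma.p_value}
    net = nets.get(lake)
    if net is not None and net.n_edges:
        present = [n for n in net.node_ids if n in clr.columns]
        if len(present) == net.n_nodes:
            summary = diet_node_summary(clr, diets, net)
            summary.to_csv(ddir / "node_summary.tsv", sep="\t", index=False)
            target = pca.otu_loadings.loc[net.node_ids, ["PC1", "PC2"]]
            target.columns = ["x", "y"]
            matched = match_layout(
                net, target, n_seeds=cfg["layout"]["n_seeds"]
            )
            matched.coords.to_csv(ddir / "layout_coords.tsv", sep="\t")
            result["layout_seed"] = matched.seed
            result["layout_ss"] = matched.ss
    return result
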