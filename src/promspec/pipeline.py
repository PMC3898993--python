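"""End-to-end orchestration: cluster, profile, detect, catalogue."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import null_threshold, similarity_matrix
from .composition import TataCatalog, bca, default_exclusion_list, scan_tata
from .config import PipelineConfig
from .pb import build_hessian, diagonalize
from .regions import (
    catalog,
    coverage_fraction,
    detect_regions,
    length_histogram,
    regions_to_bed,
)
from .repeats import cluster_coverage, parse_repeatmasker
from .seqio import drop_ambiguous, encode_ws, read_fasta, write_manifest
from .spectral import cluster_promoters

logger = logging.getLogger(__name__)


def run_pipeline(
    config: PipelineConfig,
    fasta: str | Path,
    outdir: str | Path,
    repeats: str | Path | None = None,
    sampling: str = "none",
) -> Path:
    """Run the full analysis and write all artifacts to ``outdir``.

    Stages: TATA labelling -> (optional sampling) -> all-vs-all alignment
    -> reshuffle-null threshold -> spectral clustering -> per-promoter
    chain spectra -> regular regions -> per-cluster catalogues, profiles
    and repeat coverage.  A JSON manifest records versions, seeds and the
    config hash; deterministic stages are bit-identical across reruns.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}

    records = read_fasta(fasta)
    records = drop_ambiguous(records, policy=config.allow_n, seed=config.seed)
    if len(records) < 2:
        raise RuntimeError("pipeline needs at least two unambiguous promoters")
    write_manifest(records, outdir / "sequences.tsv", source=str(fasta))

    # --- TATA labels -------------------------------------------------------
    t = time.time()
    tata_catalog = TataCatalog(
        excluded=frozenset(default_exclusion_list()), window=config.tata_window
    )
    tata = [scan_tata(r, tata_catalog) for r in records]
    pd.DataFrame(
        {
            "id": [r.promoter_id for r in tata],
            "label": [r.label for r in tata],
            "matches": [",".join(map(str, r.match_positions)) for r in tata],
        }
    ).to_csv(outdir / "tata.tsv", sep="\t", index=False)
    timings["tata"] = time.time() - t

    records = _sample(records, tata, sampling, config.seed)

    # --- similarity + clustering ------------------------------------------
    t = time.time()
    scheme = config.scoring_scheme()
    sim = similarity_matrix(records, scheme)
    sim.to_tsv(outdir / "similarity.tsv")
    theta = null_threshold(records, scheme, seed=config.seed, replicates=config.null_replicates)
    timings["align"] = time.time() - t

    t = time.time()
    assign = cluster_promoters(
        sim,
        theta,
        k_max=config.k_max,
        seed=config.seed,
        tol=config.kmeans_tol,
        restarts=config.kmeans_restarts,
        normalization=config.adjacency_norm,
    )
    labels = pd.DataFrame({"id": assign.ids, "cluster": assign.labels})
    labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)
    emb = pd.DataFrame(
        assign.embedding, columns=[f"dim{i + 1}" for i in range(assign.K)]
    )
    emb.insert(0, "id", assign.ids)
    emb.to_csv(outdir / "embedding.tsv", sep="\t", index=False)
    timings["cluster"] = time.time() - t
    logger.info("clustering done: K=%d theta=%.2f", assign.K, theta)

    # --- chain spectra + regular regions ----------------------------------
    t = time.time()
    params = config.pb_parameters()
    by_prom = {}
    all_regions = []
    for rec in records:
        spectrum = diagonalize(build_hessian(encode_ws(rec.sequence), params))
        regs = detect_regions(
            spectrum,
            rec,
            P_thr=config.P_thr,
            eps=config.eps,
            delta=config.delta,
            tol=config.tol,
            min_len=config.min_len,
        )
        by_prom[rec.id] = regs
        all_regions.extend(regs)
    regions_to_bed(all_regions, outdir / "regions.bed")
    pd.DataFrame(
        [
            {
                "id": r.promoter_id,
                "start": r.s,
                "end": r.e,
                "length": r.length,
                "sequence": r.quaternary,
                "n_support": r.n_support,
            }
            for r in all_regions
        ]
    ).to_csv(outdir / "regions.tsv", sep="\t", index=False)
    hist = length_histogram(all_regions)
    pd.DataFrame({"length": list(hist), "count": list(hist.values())}).to_csv(
        outdir / "region_lengths.tsv", sep="\t", index=False
    )
    timings["regions"] = time.time() - t

    # --- per-cluster reporting --------------------------------------------
    t = time.time()
    repeat_ivs = parse_repeatmasker(repeats) if repeats is not None else None
    label_of = assign.as_dict()
    summary = {}
    for k in sorted(set(label_of.values())):
        members = [r for r in records if label_of[r.id] == k]
        if not members:
            continue
        tag = f"cluster{k}" if k >= 0 else "unassigned"
        bca(members).to_frame().to_csv(outdir / f"bca_{tag}.tsv", sep="\t")
        cat = catalog(
            {r.id: by_prom[r.id] for r in members},
            members,
            repeat_intervals=repeat_ivs,
            top_k=config.top_k,
            overlap_rule=config.overlap_rule,
        )
        pd.DataFrame(
            [
                {
                    "sequence": e.sequence,
                    "n_promoters": e.n_promoters,
                    "promoter_pct": e.promoter_pct,
                    "n_occurrences": e.n_occurrences,
                    "mean_copies": e.mean_copies,
                    "pct_in_transposon": (
                        "NA" if e.pct_in_transposon is None else e.pct_in_transposon
                    ),
                }
                for e in cat
            ]
        ).to_csv(outdir / f"catalog_{tag}.tsv", sep="\t", index=False)
        cov = float(
            np.mean([coverage_fraction(by_prom[r.id], r.L) for r in members])
        )
        entry = {"size": len(members), "mean_regular_coverage": cov}
        if repeat_ivs is not None:
            total, per_fam = cluster_coverage(
                [iv for iv in repeat_ivs if label_of.get(iv.promoter_id) == k], members
            )
            entry["transposon_pct"] = total
            entry["transposon_families"] = per_fam
        summary[tag] = entry
    timings["report"] = time.time() - t

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_promoters": len(records),
        "theta": theta,
        "K": assign.K,
        "clusters": summary,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_s": round(time.time() - t0, 3),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def _sample(records, tata_results, sampling: str, seed: int):
    """Optional TATA-aware subsampling applied before alignment."""
    if sampling == "none":
        return records
    rng = np.random.default_rng(seed)
    is_tata = {r.promoter_id: r.is_tata for r in tata_results}
    if sampling == "random":
        idx = rng.permutation(len(records))
        return [records[i] for i in sorted(idx[: len(records)])]
    tata_recs = [r for r in records if is_tata[r.id]]
    less_recs = [r for r in records if not is_tata[r.id]]
    if sampling == "balanced":
        m = min(len(tata_recs), len(less_recs))
        chosen = list(rng.choice(len(tata_recs), m, replace=False)) + [
            len(tata_recs) + i for i in rng.choice(len(less_recs), m, replace=False)
        ]
    elif sampling == "proportional":
        return records
    else:
        raise ValueError(f"unknown sampling strategy {sampling!r}")
    pool = tata_recs + less_recs
    keep = {pool[i].id for i in chosen}
    return [r for r in records if r.id in keep]
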