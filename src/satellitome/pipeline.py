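"""End-to-end orchestration: simulate -> discover -> catalog -> quantify -> MST.

A run is fully determined by a :class:`~satellitome.config.RunConfig`: the
global seed is expanded into independent per-stage streams
(:func:`~satellitome.config.stage_rng`), and a run manifest records the config
snapshot, per-stage outputs and their checksums, so re-running from the same
config and inputs reproduces every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import catalog as catalog_mod
from . import discovery, haplonet, io, simulate
from . import quantification as quantify_mod
from .config import RunConfig, stage_rng

logger = logging.getLogger(__name__)

Pair = Tuple[str, str]


def _qual_ok(qual: str, min_char: str) -> bool:
    return not qual or min(qual) >= min_char


def load_library(
    r1: str | Path, r2: str | Path, quality_threshold: int
) -> List[Pair]:
    """Read a paired FASTQ library and apply whole-read QC.

    A pair is kept iff every base of both mates has Phred quality >= the
    threshold and neither mate contains an N.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    min_char = chr(quality_threshold + io.PHRED_OFFSET)
    pairs: List[Pair] = []
    with open(r1) as h1, open(r2) as h2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
            FastqGeneralIterator(h1), FastqGeneralIterator(h2)
        ):
            if len(s1) != len(q1) or len(s2) != len(q2):
                raise ValueError(f"sequence/quality length mismatch near {t1}")
            s1, s2 = s1.upper(), s2.upper()
            if "N" in s1 or "N" in s2:
                continue
            if _qual_ok(q1, min_char) and _qual_ok(q2, min_char):
                pairs.append((s1, s2))
    return pairs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _catalog_stage(
    candidates: Sequence[discovery.CandidateMonomer],
    libraries: Dict[str, List[Pair]],
    config: RunConfig,
):
    """Dedupe candidates, quantify them, then rank/name/partition the catalog."""
    kept = catalog_mod.dedupe_candidates(
        [c.sequence for c in candidates],
        [c.support for c in candidates],
        config.identity_thresholds.variant,
    )
    seqs = [s for s, _ in kept]
    if not seqs:
        return [], catalog_mod.HomologyPartition([], [], []), [], []
    rng_q = stage_rng(config.seed, "quantify")
    records, div = quantify_mod.quantify(
        libraries["male"], libraries["female"], seqs,
        [f"cand{i + 1}" for i in range(len(seqs))], config, rng_q,
    )
    abundances = {
        seq: (rec.abundance_male, rec.abundance_female) for seq, rec in zip(seqs, records)
    }
    monomers, partition = catalog_mod.finalize_catalog(
        seqs, abundances, config.identity_thresholds, config.name_prefix
    )
    # rename quantification records to the final catalog names
    final_name = {m.sequence: m.name for m in monomers}
    for seq, rec, dv in zip(seqs, records, div):
        rec.name = final_name[seq]
        dv.name = final_name[seq]
        rec.bias_call = quantify_mod._bias_call(rec.mf_ratio, config.mf_bias_ratio)
    order = {m.name: i for i, m in enumerate(monomers)}
    records.sort(key=lambda r: order[r.name])
    div.sort(key=lambda d: order[d.name])
    return monomers, partition, records, div


def evaluate_run(
    truth: simulate.PlantedTruth,
    monomers: Sequence[catalog_mod.SatMonomer],
    records: Sequence[quantify_mod.AbundanceRecord],
    variant_threshold: float = 0.95,
    purity_threshold: float = 0.80,
) -> Tuple[pd.DataFrame, Dict]:
    """Compare a finished run against planted truth.

    Returns a per-planted-satellite table (matched catalog entry, consensus
    identity, abundance relative errors, M/F call) and a summary with recall,
    purity and worst-case abundance error over recovered satellites.
    """
    rec_by_name = {r.name: r for r in records}
    rows = []
    matched_catalog: set = set()
    for sat in truth.satellites:
        best_name, best_ident = None, 0.0
        for m in monomers:
            ident = catalog_mod.pairwise_identity(sat.monomer, m.sequence)
            if ident > best_ident:
                best_name, best_ident = m.name, ident
        recovered = best_ident >= variant_threshold
        true_m, true_f = truth.true_abundance[sat.name]
        est_m = est_f = rel_m = rel_f = math.nan
        bias = ""
        if recovered:
            matched_catalog.add(best_name)
            rec = rec_by_name[best_name]
            est_m, est_f = rec.abundance_male, rec.abundance_female
            rel_m = abs(est_m - true_m) / true_m if true_m > 0 else math.nan
            rel_f = abs(est_f - true_f) / true_f if true_f > 0 else math.nan
            bias = rec.bias_call
        rows.append(
            {
                "planted": sat.name,
                "matched": best_name if recovered else "",
                "consensus_identity": best_ident,
                "true_abundance_male": true_m,
                "true_abundance_female": true_f,
                "est_abundance_male": est_m,
                "est_abundance_female": est_f,
                "rel_error_male": rel_m,
                "rel_error_female": rel_f,
                "true_mf_ratio": truth.true_mf_ratio[sat.name],
                "bias_call": bias,
            }
        )
    columns = [
        "planted", "matched", "consensus_identity",
        "true_abundance_male", "true_abundance_female",
        "est_abundance_male", "est_abundance_female",
        "rel_error_male", "rel_error_female", "true_mf_ratio", "bias_call",
    ]
    table = pd.DataFrame(rows, columns=columns)
    purity_ok = 0
    for m in monomers:
        if any(
            catalog_mod.pairwise_identity(sat.monomer, m.sequence) >= purity_threshold
            for sat in truth.satellites
        ):
            purity_ok += 1
    rel_errors = [
        v
        for row in rows
        if row["matched"]
        for v in (row["rel_error_male"], row["rel_error_female"])
        if not math.isnan(v)
    ]
    summary = {
        "n_planted": len(truth.satellites),
        "n_recovered": int(table["matched"].astype(bool).sum()),
        "recall": float(table["matched"].astype(bool).mean()) if rows else 0.0,
        "purity": purity_ok / len(monomers) if monomers else 1.0,
        "max_abundance_rel_error": max(rel_errors) if rel_errors else math.nan,
        "mean_consensus_identity": float(
            table.loc[table["matched"] != "", "consensus_identity"].mean()
        )
        if rows
        else math.nan,
    }
    return table, summary


def run_synthetic(
    config: RunConfig,
    outdir: str | Path,
    genome_length: int = 2_000_000,
    coverage: float = 10.0,
    gc_background: float = 0.45,
    satellites: Optional[List[simulate.PlantedSatellite]] = None,
    sim_params: Optional[simulate.ReadSimParams] = None,
    mst_monomers: Optional[List[str]] = None,
    write_reads: bool = False,
) -> Dict:
    """Full synthetic run; returns the manifest (also written to outdir).

    When *satellites* is None the default study panel is planted.  Reads are
    kept in memory; set *write_reads* to also emit the FASTQ files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = sim_params or simulate.ReadSimParams(read_length=config.read_length)
    manifest: Dict = {
        "config": dataclasses.asdict(config),
        "genome_length": genome_length,
        "coverage": coverage,
        "outputs": {},
    }

    # -- simulate ----------------------------------------------------------
    rng_sim = stage_rng(config.seed, "simulate")
    panel = satellites if satellites is not None else simulate.default_panel(rng_sim, genome_length)
    male_genome, female_genome, truth = simulate.build_genomes(
        panel, genome_length, gc_background, rng_sim
    )
    truth.to_json(outdir / "truth.json")
    io.write_fasta([("male_genome", male_genome)], outdir / "male_genome.fasta")
    io.write_fasta([("female_genome", female_genome)], outdir / "female_genome.fasta")
    n_pairs = simulate.coverage_pairs(genome_length, coverage, params.read_length)
    libraries: Dict[str, List[Pair]] = {}
    for sex, genome in (("male", male_genome), ("female", female_genome)):
        quads = list(simulate.simulate_read_pairs(genome, params, n_pairs, sex, rng_sim))
        if write_reads:
            io.write_fastq(
                [(f"{rid}/1", s1, q1) for rid, s1, q1, _, _ in quads],
                outdir / f"{sex}_R1.fastq",
            )
            io.write_fastq(
                [(f"{rid}/2", s2, q2) for rid, _, _, s2, q2 in quads],
                outdir / f"{sex}_R2.fastq",
            )
        # QC: drop pairs with any base below threshold or any N
        min_q = config.quality_threshold
        libraries[sex] = [
            (s1, s2)
            for _, s1, q1, s2, q2 in quads
            if "N" not in s1 and "N" not in s2 and min(q1) >= min_q and min(q2) >= min_q
        ]
    logger.info("simulated %d pairs/sex; QC kept male=%d female=%d",
                n_pairs, len(libraries["male"]), len(libraries["female"]))

    manifest["outputs"]["truth"] = "truth.json"

    # -- discover ----------------------------------------------------------
    rng_disc = stage_rng(config.seed, "discover")
    candidates, rounds = discovery.iterate_mining(
        libraries["male"], libraries["female"], config, rng_disc
    )
    pd.DataFrame(rounds).to_csv(outdir / "rounds.tsv", sep="\t", index=False)
    io.write_fasta(
        [(f"cand{i + 1}_round{c.round_found}", c.sequence) for i, c in enumerate(candidates)],
        outdir / "candidates.fasta",
    )

    # -- catalog + quantify ------------------------------------------------
    monomers, partition, records, div = _catalog_stage(candidates, libraries, config)
    io.write_catalog(monomers, outdir / "catalog.fasta", outdir / "catalog.tsv")
    quantify_mod.abundance_table(records).to_csv(outdir / "abundance.tsv", sep="\t", index=False)
    part_rows = []
    variant_id = {n: f"V{i + 1}" for i, g in enumerate(partition.variant_groups) for n in g}
    family_id = {n: f"F{i + 1}" for i, g in enumerate(partition.family_groups) for n in g}
    for m in monomers:
        part_rows.append(
            {
                "name": m.name,
                "variant_id": variant_id.get(m.name, ""),
                "family_id": family_id.get(m.name, ""),
                "superfamily_label": partition.superfamily_labels.get(m.name, ""),
            }
        )
    pd.DataFrame(part_rows).to_csv(outdir / "partition.tsv", sep="\t", index=False)
    land_dir = outdir / "landscapes"
    land_dir.mkdir(exist_ok=True)
    for dv in div:
        quantify_mod.landscape_table(dv).to_csv(
            land_dir / f"{dv.name}.tsv", sep="\t", index=False
        )

    # -- haplotype networks ------------------------------------------------
    rng_h = stage_rng(config.seed, "haplonet")
    eligible = [
        m for m in monomers
        if m.rul <= config.mst_max_monomer_length
        and (mst_monomers is None or m.name in mst_monomers)
    ]
    for m in eligible:
        haps = haplonet.extract_haplotypes(
            libraries["male"], libraries["female"], m.sequence, config, rng_h
        )
        if not haps:
            continue
        net = haplonet.build_mst(haps, m.name)
        haplonet.write_network(net, outdir / f"mst_{m.name}.graphml")

    # -- evaluate vs planted truth ----------------------------------------
    table, summary = evaluate_run(
        truth, monomers, records, config.identity_thresholds.variant
    )
    table.to_csv(outdir / "evaluation.tsv", sep="\t", index=False)
    manifest["evaluation_summary"] = summary

    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def run_from_fastq(
    config: RunConfig,
    outdir: str | Path,
    male_r1: str | Path,
    male_r2: str | Path,
    female_r1: str | Path,
    female_r2: str | Path,
    mst_monomers: Optional[List[str]] = None,
) -> Dict:
    """Discovery/catalog/quantify/MST on user-supplied paired FASTQ libraries."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    libraries = {
        "male": load_library(male_r1, male_r2, config.quality_threshold),
        "female": load_library(female_r1, female_r2, config.quality_threshold),
    }
    manifest: Dict = {"config": dataclasses.asdict(config), "outputs": {}}
    rng_disc = stage_rng(config.seed, "discover")
    candidates, rounds = discovery.iterate_mining(
        libraries["male"], libraries["female"], config, rng_disc
    )
    pd.DataFrame(rounds).to_csv(outdir / "rounds.tsv", sep="\t", index=False)
    monomers, partition, records, div = _catalog_stage(candidates, libraries, config)
    io.write_catalog(monomers, outdir / "catalog.fasta", outdir / "catalog.tsv")
    quantify_mod.abundance_table(records).to_csv(outdir / "abundance.tsv", sep="\t", index=False)
    rng_h = stage_rng(config.seed, "haplonet")
    for m in monomers:
        if m.rul > config.mst_max_monomer_length:
            continue
        if mst_monomers is not None and m.name not in mst_monomers:
            continue
        haps = haplonet.extract_haplotypes(
            libraries["male"], libraries["female"], m.sequence, config, rng_h
        )
        if haps:
            net = haplonet.build_mst(haps, m.name)
            haplonet.write_network(net, outdir / f"mst_{m.name}.graphml")
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
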