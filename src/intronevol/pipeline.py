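"""Stage functions behind the command-line interface.

Each stage reads the TSV artifacts of the previous one from a run
directory and writes its own, so any stage can be re-run in isolation and
a manifest records the parameters and seeds that produced every file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dollo import ROOT_AMBIGUOUS, reconstruct, summarize, genes_with_both
from .homology import build_sites, classify_coding_change, detect_unspliced_insertions
from .io_formats import read_gene_models, read_protein_msa, read_tree
from .nmd import annotate_introns, fit_ptc_model, phase_stop_constraint_report
from .position import intron_codon_usage, two_sample_chisq, uniformity_chisq, usage_correlation
from .repeats import find_junction_repeats
from .simulate import (
    SimulationParams,
    SimulationResult,
    read_codon_usage,
    simulate_turnover,
    synthetic_codon_usage,
    write_codon_usage,
    write_dataset,
)
from .splice import bootstrap_statistic

logger = logging.getLogger(__name__)


class MissingArtifact(FileNotFoundError):
    pass


def _need(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifact(f"{path} not found; run the '{producer}' stage first")
    return path


def _update_manifest(outdir: Path, stage: str, payload: dict) -> None:
    manifest_path = outdir / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest.setdefault("version", __version__)
    manifest[stage] = payload
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")


def stage_simulate(outdir: str | Path, **param_overrides) -> SimulationResult:
    outdir = Path(outdir)
    params = SimulationParams(**param_overrides)
    result = simulate_turnover(params)
    datadir = outdir / "data"
    datadir.mkdir(parents=True, exist_ok=True)
    write_dataset(result, datadir)
    _update_manifest(outdir, "simulate", {"params": vars(params), "seed": params.seed})
    return result


def load_dataset(datadir: str | Path):
    datadir = Path(datadir)
    tree = read_tree(_need(datadir / "tree.nwk", "simulate"))
    species = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    models = {}
    for sp in species:
        gff = _need(datadir / f"{sp}.gff3", "simulate")
        fa = _need(datadir / f"{sp}.fa", "simulate")
        models[sp] = read_gene_models(gff, fa, sp)
    msas = {
        p.stem: read_protein_msa(p) for p in sorted((datadir / "msa").glob("*.fa"))
    }
    return tree, species, models, msas


def stage_homology(
    outdir: str | Path,
    slack: int = 0,
    min_aa: int = 15,
    window: int = 10,
) -> None:
    outdir = Path(outdir)
    tree, species, models, msas = load_dataset(outdir / "data")
    sites = build_sites(models, msas, species, slack=slack)

    pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "group": s.group_id,
                "column": s.column,
                "phase": s.phase,
                "presence": s.presence_string(species),
                "present_species": ",".join(sp for sp in species if s.presence[sp]),
            }
            for s in sites
        ],
        columns=["site_id", "group", "column", "phase", "presence", "present_species"],
    ).to_csv(outdir / "sites.tsv", sep="\t", index=False)

    intron_rows = []
    for s in sites:
        for intron in s.member_introns:
            intron_rows.append(
                {
                    "site_id": s.site_id,
                    "group": s.group_id,
                    "species": intron.species,
                    "index": intron.index,
                    "start": intron.start,
                    "end": intron.end,
                    "length": intron.length,
                    "phase": intron.phase,
                    "donor6": intron.donor6,
                    "acceptor3": intron.acceptor3,
                    "cds_offset": intron.cds_offset,
                    "cds_length": intron.cds_length,
                    "seq": intron.seq,
                }
            )
    pd.DataFrame(
        intron_rows,
        columns=[
            "site_id", "group", "species", "index", "start", "end", "length",
            "phase", "donor6", "acceptor3", "cds_offset", "cds_length", "seq",
        ],
    ).to_csv(outdir / "introns.tsv", sep="\t", index=False)

    changes = []
    for s in sites:
        if any(s.presence.values()) and not all(s.presence.values()):
            cc = classify_coding_change(s, msas[s.group_id], window=window)
            changes.append(
                {
                    "site_id": cc.site_id,
                    "n_aa_delta": cc.n_aa_delta,
                    "change_class": cc.change_class,
                }
            )
    pd.DataFrame(changes, columns=["site_id", "n_aa_delta", "change_class"]).to_csv(
        outdir / "coding_changes.tsv", sep="\t", index=False
    )
    detect_unspliced_insertions(msas, sites, min_aa=min_aa).to_csv(
        outdir / "insertions.tsv", sep="\t", index=False
    )
    _update_manifest(
        outdir, "homology", {"slack": slack, "min_aa": min_aa, "window": window}
    )


def _load_sites(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(
        _need(outdir / "sites.tsv", "homology"),
        sep="\t",
        dtype={"presence": str},
        keep_default_na=False,
    )


def stage_events(outdir: str | Path, n_genes: int | None = None) -> None:
    outdir = Path(outdir)
    tree = read_tree(_need(outdir / "data" / "tree.nwk", "simulate"))
    species = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    sites_df = _load_sites(outdir)

    from .homology import IntronSite

    sites = [
        IntronSite(
            group_id=row["group"],
            column=int(row["column"]),
            phase=int(row["phase"]),
            presence={sp: ch == "1" for sp, ch in zip(species, row["presence"])},
        )
        for _, row in sites_df.iterrows()
    ]
    recon = reconstruct(sites, tree)
    events = recon.events_frame()
    events.to_csv(outdir / "events.tsv", sep="\t", index=False)
    if n_genes is None:
        n_genes = sites_df["group"].nunique()
    rates = summarize(recon, n_genes=n_genes)
    rates.to_csv(outdir / "rates.tsv", sep="\t", index=False)
    classes = pd.DataFrame(
        {
            "site_id": [s.site_id for s in recon.sites],
            "class": [
                "conserved" if s.is_root_ambiguous else "novel" for s in recon.sites
            ],
            "n_losses": [len(s.loss_branches) for s in recon.sites],
        }
    )
    classes.to_csv(outdir / "site_classes.tsv", sep="\t", index=False)
    pd.DataFrame({"group": genes_with_both(recon)}).to_csv(
        outdir / "genes_with_both.tsv", sep="\t", index=False
    )
    _update_manifest(
        outdir,
        "events",
        {
            "n_genes": n_genes,
            "n_sites": len(sites),
            "n_root_ambiguous": recon.n_root_ambiguous,
        },
    )


def _labelled_site_introns(outdir: Path) -> pd.DataFrame:
    """One representative intron per site (first carrier alphabetically),
    joined with its novel/conserved class."""
    introns = pd.read_csv(_need(outdir / "introns.tsv", "homology"), sep="\t")
    classes = pd.read_csv(_need(outdir / "site_classes.tsv", "events"), sep="\t")
    reps = (
        introns.sort_values(["site_id", "species"])
        .groupby("site_id", as_index=False)
        .first()
    )
    return reps.merge(classes, on="site_id", how="inner")


def stage_splice(
    outdir: str | Path,
    B: int = 10_000,
    seed: int = 0,
    focal_n: int | None = None,
    resample_focal: bool = False,
) -> pd.DataFrame:
    outdir = Path(outdir)
    table = _labelled_site_introns(outdir)
    focal = table[table["class"] == "novel"]
    reference = table[table["class"] == "conserved"]
    if focal.empty or reference.empty:
        raise ValueError("need both novel and conserved introns for the bootstrap")
    rows = []
    for stat, focal_col, ref_col in [
        ("donor_consensus_frac", "donor6", "donor6"),
        ("acceptor_consensus_frac", "acceptor3", "acceptor3"),
        ("distinct_donor_motifs", "donor6", "donor6"),
    ]:
        summary = bootstrap_statistic(
            reference[ref_col].tolist(),
            focal[focal_col].tolist(),
            stat,
            B=B,
            focal_n=focal_n,
            seed=seed,
            resample_focal=resample_focal,
        )
        rows.append(vars(summary))
    out = pd.DataFrame(rows)
    out.to_csv(outdir / "bootstrap.tsv", sep="\t", index=False)
    _update_manifest(outdir, "splice", {"B": B, "seed": seed, "focal_n": focal_n})
    return out


def stage_nmd(
    outdir: str | Path, include_boundary: bool = False, log_length: bool = False
) -> None:
    outdir = Path(outdir)
    table = _labelled_site_introns(outdir)
    annotated = annotate_introns(table, include_boundary=include_boundary)
    annotated.rename(columns={"group": "gene", "class": "group"}, inplace=True)
    annotated.drop(columns=["seq"]).to_csv(
        outdir / "nmd_annotations.tsv", sep="\t", index=False
    )
    result = fit_ptc_model(annotated, log_length=log_length)
    result.coef_table.to_csv(outdir / "nmd_model.tsv", sep="\t", index=False)
    contrasts = result.contrasts.copy()
    contrasts["pseudo_r2_mcfadden"] = result.pseudo_r2
    contrasts["standard_fit"] = result.standard_fit
    contrasts.to_csv(outdir / "nmd_contrasts.tsv", sep="\t", index=False)
    phase_stop_constraint_report(annotated).to_csv(
        outdir / "nmd_phase_report.tsv", sep="\t", index=False
    )
    _update_manifest(
        outdir,
        "nmd",
        {
            "include_boundary": include_boundary,
            "log_length": log_length,
            "n_per_cell": result.n_per_cell,
        },
    )


def stage_repeats(
    outdir: str | Path, flank: int = 50, word: int = 8, max_mismatches: int = 2
) -> pd.DataFrame:
    outdir = Path(outdir)
    datadir = outdir / "data"
    tree, species, models, _ = load_dataset(datadir)
    classes = pd.read_csv(_need(outdir / "site_classes.tsv", "events"), sep="\t")
    novel_ids = set(classes.loc[classes["class"] == "novel", "site_id"])
    introns = pd.read_csv(_need(outdir / "introns.tsv", "homology"), sep="\t")
    novel = introns[introns["site_id"].isin(novel_ids)].sort_values(
        ["site_id", "species"]
    ).groupby("site_id", as_index=False).first()

    from Bio import SeqIO
    from Bio.Seq import Seq

    contig_seqs: dict[str, dict[str, str]] = {}
    for sp in species:
        contig_seqs[sp] = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(datadir / f"{sp}.fa"), "fasta")
        }
    model_index = {
        (sp, m.gene_id): m for sp in species for m in models[sp]
    }
    rows = []
    for _, r in novel.iterrows():
        model = model_index.get((r["species"], r["group"]))
        if model is None:
            continue
        contig = contig_seqs[r["species"]][model.contig]
        gstart, gend = model.span
        lo = max(0, gstart - flank)
        hi = min(len(contig), gend + flank)
        region = contig[lo:hi]
        if model.strand == "-":
            region = str(Seq(region).reverse_complement())
            offset = hi - gend  # 5' pad length on the coding strand
        else:
            offset = gstart - lo
        hits = find_junction_repeats(
            region,
            offset + int(r["start"]),
            offset + int(r["end"]),
            flank=flank,
            word=word,
            max_mismatches=max_mismatches,
        )
        for h in hits:
            rows.append(
                {
                    "site_id": r["site_id"],
                    "species": r["species"],
                    "matches": h.matches,
                    "span": h.span,
                    "identity": h.identity,
                    "copyA_start": h.copyA_start,
                    "copyA_end": h.copyA_end,
                    "copyB_start": h.copyB_start,
                    "copyB_end": h.copyB_end,
                    "overlaps_5ss": h.overlaps_5ss,
                    "overlaps_3ss": h.overlaps_3ss,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "site_id", "species", "matches", "span", "identity",
            "copyA_start", "copyA_end", "copyB_start", "copyB_end",
            "overlaps_5ss", "overlaps_3ss",
        ],
    )
    out.to_csv(outdir / "repeats.tsv", sep="\t", index=False)
    _update_manifest(
        outdir,
        "repeats",
        {"flank": flank, "word": word, "max_mismatches": max_mismatches},
    )
    return out


def stage_position(
    outdir: str | Path, n_bins: int = 2, usage_table: str | Path | None = None
) -> pd.DataFrame:
    outdir = Path(outdir)
    table = _labelled_site_introns(outdir)
    table["relative_position"] = table["cds_offset"] / table["cds_length"]
    table[["site_id", "group", "species", "relative_position", "class"]].to_csv(
        outdir / "positions.tsv", sep="\t", index=False
    )
    rows = []
    by_class = {
        k: v["relative_position"].to_numpy() for k, v in table.groupby("class")
    }
    lost = table[table["n_losses"] > 0]["relative_position"].to_numpy()
    for name, pos in list(by_class.items()) + [("lost", lost)]:
        if len(pos) < 2:
            continue
        chi2, df, p = uniformity_chisq(pos, n_bins=n_bins)
        rows.append({"test": f"uniformity_{name}", "chi2": chi2, "df": df, "p": p})
    if "novel" in by_class and "conserved" in by_class:
        chi2, df, p = two_sample_chisq(by_class["novel"], by_class["conserved"])
        rows.append({"test": "novel_vs_conserved", "chi2": chi2, "df": df, "p": p})

    reference = (
        read_codon_usage(usage_table) if usage_table else synthetic_codon_usage()
    )
    novel = table[table["class"] == "novel"]
    if len(novel):
        usage = intron_codon_usage(novel)
        write_codon_usage(usage, outdir / "novel_codon_usage.tsv")
        rho, p = usage_correlation(usage, reference)
        rows.append({"test": "usage_spearman_novel", "chi2": rho, "df": -1, "p": p})
    out = pd.DataFrame(rows, columns=["test", "chi2", "df", "p"])
    out.to_csv(outdir / "position_tests.tsv", sep="\t", index=False)
    _update_manifest(outdir, "position", {"n_bins": n_bins})
    return out


def stage_all(outdir: str | Path, config: dict | None = None) -> None:
    """Chain every analysis stage on an existing simulated/real dataset."""
    cfg = config or {}
    stage_homology(outdir, **cfg.get("homology", {}))
    stage_events(outdir, **cfg.get("events", {}))
    stage_splice(outdir, **cfg.get("splice", {}))
    stage_nmd(outdir, **cfg.get("nmd", {}))
    stage_repeats(outdir, **cfg.get("repeats", {}))
    stage_position(outdir, **cfg.get("position", {}))
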