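"""End-to-end orchestration: FASTQ -> counts -> CPM/Venn -> DE -> targets.

Runs the stages in order (trim, align, classify, count, CPM, expressed
sets, differential expression, thresholds, target prediction, enrichment),
persists every intermediate as TSV/JSON under the output directory and
keeps a per-stage record count log so no reads are silently dropped.
Outputs are deterministic: rerunning an identical configuration produces
byte-identical files.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO

from . import de as de_mod
from . import targets as tg
from .align import profile_fastqs
from .de import apply_thresholds, cpm, de_test, expressed_sets
from .reference import ReferenceSet, read_reference
from .targets import predict_targets, hypergeom_enrich, read_gmt

logger = logging.getLogger("tsrnakit")


@dataclass
class PipelineConfig:
    fastqs: list[str]                  # one FASTQ per sample
    samples: list[str]
    groups: list[str]                  # e.g. Ctrl / Cd per sample
    reference_fasta: str
    reference_sidecar: str
    outdir: str
    adapter3: str
    utr_fasta: Optional[str] = None
    gmt: Optional[str] = None
    cpm_expressed: float = de_mod.CPM_EXPRESSED
    lfc_threshold: float = de_mod.LFC_THRESHOLD
    alpha: float = de_mod.ALPHA
    use_adjusted_p: bool = False       # threshold padj instead of raw p
    duplex_threshold: float = tg.DUPLEX_THRESHOLD
    rng_seed: int = 0

    def validate(self) -> None:
        if not (len(self.fastqs) == len(self.samples) == len(self.groups)):
            raise ValueError("fastqs, samples and groups must align")
        for p in [*self.fastqs, self.reference_fasta, self.reference_sidecar,
                  *( [self.utr_fasta] if self.utr_fasta else []),
                  *( [self.gmt] if self.gmt else [])]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        for name, v in (("cpm_expressed", self.cpm_expressed),
                        ("lfc_threshold", self.lfc_threshold),
                        ("alpha", self.alpha),
                        ("duplex_threshold", self.duplex_threshold)):
            if v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SummaryBundle:
    """The tabular backing of the study's summary figures."""

    subtype_counts: pd.DataFrame       # subtype x group (expressed species)
    isodecoder_counts: pd.DataFrame    # family x subtype (expressed anywhere)
    length_distribution: pd.DataFrame  # length x subtype x group frequencies
    venn: dict                         # common / <g>_only sizes
    de_table: pd.DataFrame
    candidates: pd.DataFrame
    log: dict = field(default_factory=dict)


def summarize_subtypes(species: pd.DataFrame,
                       expressed_by_group: dict[str, set[str]]) -> pd.DataFrame:
    """Species counts per subtype over each group's expressed set."""
    cols = {}
    for group, ids in expressed_by_group.items():
        sub = species.loc[sorted(ids)]["subtype"].value_counts()
        cols[group] = sub
    out = pd.DataFrame(cols).fillna(0).astype(int)
    out.index.name = "subtype"
    return out.sort_index()


def venn_counts(sets: dict[str, set[str]]) -> dict[str, int]:
    return {k: len(v) for k, v in sets.items()}


def _expressed_by_group(cpm_df: pd.DataFrame, groups: Sequence[str],
                        threshold: float) -> dict[str, set[str]]:
    out = {}
    for g in dict.fromkeys(groups):
        cols = [c for c, lab in zip(cpm_df.columns, groups) if lab == g]
        mean = cpm_df[cols].mean(axis=1)
        out[g] = set(cpm_df.index[mean >= threshold])
    return out


def _family_of(species: pd.DataFrame) -> pd.Series:
    genes = species["supporting_genes"].str.split(",").str[0]
    return genes.str.rsplit("-", n=1).str[0]


def run_pipeline(config: PipelineConfig) -> SummaryBundle:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: dict = {"seed": config.rng_seed, "stages": {}}

    refs = read_reference(config.reference_fasta, config.reference_sidecar)
    run_log["stages"]["reference"] = {"genes": len(refs)}

    prof = profile_fastqs(config.fastqs, config.samples, refs, config.adapter3)
    counts, species = prof.counts, prof.species
    run_log["stages"]["profile"] = prof.log
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    species.to_csv(outdir / "species.tsv", sep="\t")

    if counts.empty or counts.to_numpy().sum() == 0:
        warnings.warn("no aligned reads; writing empty outputs")
        empty = pd.DataFrame()
        for name in ("cpm.tsv", "de.tsv", "candidates.tsv"):
            empty.to_csv(outdir / name, sep="\t")
        venn = {}
        bundle = SummaryBundle(
            subtype_counts=pd.DataFrame(), isodecoder_counts=pd.DataFrame(),
            length_distribution=pd.DataFrame(), venn=venn,
            de_table=empty, candidates=empty, log=run_log)
        (outdir / "summary.json").write_text(json.dumps(
            {"venn": venn, "log": run_log}, indent=2, sort_keys=True))
        return bundle

    cpm_df = cpm(counts)
    cpm_df.to_csv(outdir / "cpm.tsv", sep="\t")
    run_log["stages"]["cpm"] = {"species": int(len(cpm_df))}

    sets = expressed_sets(cpm_df, list(config.groups), config.cpm_expressed)
    venn = venn_counts(sets)
    by_group = _expressed_by_group(cpm_df, config.groups, config.cpm_expressed)
    subtype_counts = summarize_subtypes(species, by_group)
    subtype_counts.to_csv(outdir / "subtype_counts.tsv", sep="\t")

    expressed_any = sorted(set().union(*by_group.values())) if by_group else []
    expressed_species = species.loc[expressed_any]
    iso = (expressed_species.assign(family=_family_of(expressed_species))
           .groupby(["family", "subtype"]).size().unstack(fill_value=0)
           .sort_index())
    iso.to_csv(outdir / "isodecoder_counts.tsv", sep="\t")

    length_rows = []
    for group, ids in by_group.items():
        sub = species.loc[sorted(ids)]
        tab = sub.groupby(["length", "subtype"]).size().rename("n").reset_index()
        tab["group"] = group
        length_rows.append(tab)
    length_dist = (pd.concat(length_rows, ignore_index=True)
                   if length_rows else pd.DataFrame())
    length_dist.to_csv(outdir / "length_distribution.tsv", sep="\t", index=False)

    group_sizes = pd.Series(list(config.groups)).value_counts()
    if len(group_sizes) == 2 and group_sizes.min() >= 2:
        de_table = de_test(counts, list(config.groups),
                           lfc_threshold=config.lfc_threshold,
                           alpha=config.alpha,
                           use_adjusted=config.use_adjusted_p)
        candidates = apply_thresholds(de_table, config.lfc_threshold,
                                      config.alpha, config.use_adjusted_p)
    else:
        warnings.warn("fewer than 2 samples per group; skipping DE")
        de_table = pd.DataFrame()
        candidates = pd.DataFrame()
    de_table.to_csv(outdir / "de.tsv", sep="\t")
    candidates.to_csv(outdir / "candidates.tsv", sep="\t")
    run_log["stages"]["de"] = {
        "tested": int(de_table["tested"].sum()) if "tested" in de_table else 0,
        "candidates": int(len(candidates)),
    }

    target_table = pd.DataFrame(columns=["tsrna_id", "gene_id"])
    enrich_table = pd.DataFrame()
    if config.utr_fasta and len(candidates):
        utr_db = {rec.id: str(rec.seq).upper().replace("U", "T")
                  for rec in SeqIO.parse(config.utr_fasta, "fasta")}
        cand_seqs = {i: species.loc[i, "seq"] for i in candidates.index
                     if i in species.index and len(species.loc[i, "seq"]) >= 8}
        preds = predict_targets(cand_seqs, utr_db,
                                threshold=config.duplex_threshold)
        rows = [{"tsrna_id": t, "gene_id": g}
                for t, p in sorted(preds.items())
                for g in sorted(p.targets)]
        target_table = pd.DataFrame(rows, columns=["tsrna_id", "gene_id"])
        run_log["stages"]["targets"] = {
            "tsrnas": len(cand_seqs),
            "target_genes": int(target_table["gene_id"].nunique()),
        }
        if config.gmt is not None:
            gene_sets = read_gmt(config.gmt)
            union_targets = sorted(set(target_table["gene_id"]))
            enrich_table = hypergeom_enrich(union_targets, gene_sets,
                                            universe=utr_db.keys())
            run_log["stages"]["enrichment"] = {
                "terms": int(len(enrich_table)),
                "significant": int((enrich_table["pvalue"] < config.alpha).sum())
                if len(enrich_table) else 0,
            }
    target_table.to_csv(outdir / "targets.tsv", sep="\t", index=False)
    enrich_table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    (outdir / "summary.json").write_text(json.dumps(
        {"venn": venn, "subtype_counts": subtype_counts.to_dict(),
         "log": run_log}, indent=2, sort_keys=True, default=int))
    logger.info("pipeline complete: %s", run_log)
    return SummaryBundle(
        subtype_counts=subtype_counts, isodecoder_counts=iso,
        length_distribution=length_dist, venn=venn, de_table=de_table,
        candidates=candidates, log=run_log)
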