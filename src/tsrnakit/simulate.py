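"""Synthetic tsRNA study generator: references, truth, counts and FASTQ.

Emulates the structure of a two-condition sperm small-RNA sequencing
experiment: a set of tRNA isodecoder families, a population of tsRNA
species with subtype-specific placement (tRF 14-30 nt, halves 31-40 nt,
tRF-1 from the 3' trailer), negative-binomial counts with planted
|log2FC| effects, and 50-bp single-end reads carrying a 3' adapter and
substitution errors.

Every generated species is validated against the production aligner,
classifier and namer: a candidate fragment is accepted only if it trims
and maps back to exactly the species being constructed, so an error-free
run of the read-processing pipeline recovers the truth manifest exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import (ConfigError, FragmentAligner, call_species, trim_adapter)
from .reference import ReferenceSet, TRNAGeneRecord

# default subtype mix: mature-derived species dominate, 5' species most
# abundant, a small tRF-1 class — the shape seen in sperm tsRNA profiles
DEFAULT_MIX = {
    "tRF-5a": 0.08, "tRF-5b": 0.17, "tRF-5c": 0.20, "tiRNA-5": 0.25,
    "tRF-3a": 0.10, "tRF-3b": 0.08, "tiRNA-3": 0.07, "tRF-1": 0.05,
}

# anticodon families to draw from (amino acid, anticodon as DNA)
FAMILY_POOL = [
    ("Ala", "AGC"), ("Ala", "CGC"), ("Arg", "TCT"), ("Asp", "GTC"),
    ("Cys", "GCA"), ("Gln", "CTG"), ("Glu", "CTC"), ("Glu", "TTC"),
    ("Gly", "ACC"), ("Gly", "CCC"), ("Gly", "GCC"), ("Gly", "TCC"),
    ("His", "GTG"), ("Leu", "CAA"), ("Leu", "TAG"), ("Lys", "CTT"),
    ("Lys", "TTT"), ("Met", "CAT"), ("Phe", "GAA"), ("Pro", "AGG"),
    ("Pro", "CGG"), ("Ser", "AGA"), ("Ser", "GCT"), ("Thr", "AGT"),
    ("Tyr", "GTA"), ("Val", "AAC"), ("Val", "CAC"), ("Trp", "CCA"),
]

ILLUMINA_SMALL_RNA_ADAPTER = "AGATCGGAAGAGCACACGTCT"


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment."""

    n_families: int = 15
    isodecoders_per_family: int = 3
    n_species: int = 150
    subtype_mix: dict = field(default_factory=lambda: dict(DEFAULT_MIX))
    depth: float = 100_000.0          # expected aligned reads per sample
    error_rate: float = 0.001         # per-base substitution probability
    adapter3: str = ILLUMINA_SMALL_RNA_ADAPTER
    read_len: int = 50                # 50-bp single-end
    n_per_group: int = 5
    planted_effects: list = field(default_factory=list)  # (selector, log2FC)
    nb_dispersion: float = 0.1        # var = mu + dispersion * mu^2
    rng_seed: int = 0
    leader_len: int = 20
    trailer_len: int = 25

    def validate(self) -> None:
        total = sum(self.subtype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"subtype_mix sums to {total}, expected 1")
        unknown = set(self.subtype_mix) - set(DEFAULT_MIX)
        if unknown:
            raise ConfigError(f"unknown subtypes in mix: {sorted(unknown)}")
        if self.depth <= 0:
            raise ConfigError("depth must be > 0")
        if not (0 <= self.error_rate < 0.1):
            raise ConfigError("error_rate must be in [0, 0.1)")
        if self.read_len < 40:
            raise ConfigError("read_len must be >= 40")
        if self.subtype_mix.get("tRF-1", 0) > 0 and self.trailer_len < 14:
            raise ConfigError("tRF-1 requested but trailer shorter than 14 nt")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")


@dataclass
class TruthSpecies:
    tsrna_id: str
    subtype: str
    seq: str
    gene_ids: tuple[str, ...]
    start: int
    end: int
    source: str
    rel_abundance: float
    log2fc: float = 0.0

    def group_means(self, depth: float) -> tuple[float, float]:
        """(ctrl, treated) expected counts; the effect is split symmetrically."""
        base = depth * self.rel_abundance
        return base * 2.0 ** (-self.log2fc / 2), base * 2.0 ** (self.log2fc / 2)


@dataclass
class TruthManifest:
    species: list[TruthSpecies]
    config: SimConfig

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sp in self.species:
            m_ctrl, m_cd = sp.group_means(self.config.depth)
            rows.append({
                "tsrna_id": sp.tsrna_id, "subtype": sp.subtype,
                "length": sp.end - sp.start + 1, "seq": sp.seq,
                "genes": ",".join(sp.gene_ids), "start": sp.start,
                "end": sp.end, "source": sp.source,
                "rel_abundance": sp.rel_abundance, "log2fc": sp.log2fc,
                "mean_ctrl": m_ctrl, "mean_cd": m_cd,
            })
        return pd.DataFrame(rows).set_index("tsrna_id")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _make_reference(cfg: SimConfig, rng: np.random.Generator) -> ReferenceSet:
    """Random isodecoder families: shared consensus + a few point changes."""
    if cfg.n_families > len(FAMILY_POOL):
        raise ConfigError(f"at most {len(FAMILY_POOL)} families supported")
    fam_idx = rng.choice(len(FAMILY_POOL), size=cfg.n_families, replace=False)
    genes: list[TRNAGeneRecord] = []
    for fi in fam_idx:
        aa, anticodon = FAMILY_POOL[fi]
        body_len = int(rng.integers(70, 75))       # spliced body length
        a_start = int(rng.integers(32, 37))        # anticodon position
        consensus = np.frombuffer(_random_seq(rng, body_len).encode(),
                                  dtype=np.uint8).copy()
        consensus[a_start - 1 : a_start + 2] = np.frombuffer(
            anticodon.encode(), dtype=np.uint8)
        has_intron = rng.random() < 0.1
        for iso in range(1, cfg.isodecoders_per_family + 1):
            body = consensus.copy()
            if iso > 1:
                # mutate a handful of positions outside the anticodon
                n_mut = int(rng.integers(2, 6))
                pos = rng.choice(body_len, size=n_mut, replace=False)
                for p in pos:
                    if a_start - 1 <= p <= a_start + 1:
                        continue
                    body[p] = rng.choice(_BASES[_BASES != body[p]])
            spliced = body.tobytes().decode()
            if has_intron:
                # insert a 10-nt intron after the anticodon loop
                ins_at = a_start + 8
                intron_seq = _random_seq(rng, 10)
                body_seq = spliced[:ins_at] + intron_seq + spliced[ins_at:]
                intron = (ins_at + 1, ins_at + 10)
            else:
                body_seq, intron = spliced, None
            genes.append(TRNAGeneRecord(
                gene_id=f"{aa}-{anticodon}-{iso}", amino_acid=aa,
                anticodon=anticodon, isodecoder_index=iso, body_seq=body_seq,
                anticodon_start=a_start, intron=intron,
                leader_seq=_random_seq(rng, cfg.leader_len),
                trailer_seq=_random_seq(rng, cfg.trailer_len),
            ))
    return ReferenceSet(genes=genes)


def _candidate_coords(subtype: str, L: int, a_start: int,
                      trailer_len: int, body_end: int) -> list[tuple[int, int]]:
    """All (start, end) placements a host tRNA offers for one subtype."""
    if subtype == "tRF-5a":
        return [(1, e) for e in range(14, 17)]
    if subtype == "tRF-5b":
        return [(1, e) for e in range(17, 25)]
    if subtype == "tRF-5c":
        return [(1, e) for e in range(25, 33)]
    if subtype == "tiRNA-5":
        # 5' half: cut within the anticodon loop
        return [(1, e) for e in range(a_start - 1, a_start + 3)
                if 33 <= e <= 40]
    if subtype == "tRF-3a":
        return [(L - k + 1, L) for k in range(14, 21)]
    if subtype == "tRF-3b":
        return [(L - k + 1, L) for k in range(21, 31)]
    if subtype == "tiRNA-3":
        lo = max(L - 40 + 1, a_start + 1)
        hi = min(L - 31 + 1, a_start + 3)
        return [(s, L) for s in range(lo, hi + 1)]
    if subtype == "tRF-1":
        return [(body_end + 1, body_end + k)
                for k in range(14, min(40, trailer_len) + 1)]
    raise ConfigError(f"unknown subtype {subtype!r}")


def enumerate_species(refs: ReferenceSet, cfg: SimConfig,
                      aligner: Optional[FragmentAligner] = None,
                      ) -> dict[str, list[TruthSpecies]]:
    """All distinct, unambiguous tsRNA species a reference can host.

    Every candidate fragment must survive adapter trimming intact and be
    recovered by the production aligner/namer at exactly its intended
    placement and subtype (closure property); fragments seen before (e.g.
    shared across isodecoders) collapse into one multi-gene species.
    """
    aligner = aligner or FragmentAligner(refs)
    pools: dict[str, list[TruthSpecies]] = {s: [] for s in DEFAULT_MIX}
    seen_seqs: set[str] = set()
    seen_ids: set[str] = set()
    for gene in refs.genes:
        mat = refs.matures[gene.gene_id]
        pre = refs.precursors[gene.gene_id]
        for subtype in pools:
            coords = _candidate_coords(
                subtype, mat.length, mat.anticodon_span[0],
                pre.length - pre.body_span[1], pre.body_span[1])
            for start, end in coords:
                if subtype == "tRF-1":
                    frag = pre.seq[start - 1 : end]
                else:
                    frag = mat.seq[start - 1 : end]
                if frag in seen_seqs:
                    continue
                seen_seqs.add(frag)
                # must survive adapter trimming intact
                read = (frag + cfg.adapter3 + "A" * cfg.read_len)[: cfg.read_len]
                if trim_adapter(read, cfg.adapter3)[0] != frag:
                    continue
                call = call_species(frag, aligner)
                if (call is None or call.subtype != subtype
                        or call.start != start or call.end != end
                        or call.seq != frag or call.tsrna_id in seen_ids):
                    continue
                seen_ids.add(call.tsrna_id)
                pools[subtype].append(TruthSpecies(
                    tsrna_id=call.tsrna_id, subtype=subtype, seq=frag,
                    gene_ids=call.supporting_genes, start=start, end=end,
                    source="precursor" if subtype == "tRF-1" else "mature",
                    rel_abundance=0.0))
    return pools


def simulate_truth(cfg: SimConfig) -> tuple[TruthManifest, ReferenceSet]:
    """Generate the reference set and the ground-truth species population.

    Subtype counts are drawn from a multinomial over ``subtype_mix`` and
    species are sampled without replacement from the pool of closure-safe
    placements the reference offers, so empirical subtype frequencies are
    exactly binomial around the mix.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    refs = _make_reference(cfg, rng)
    pools = enumerate_species(refs, cfg)
    subtypes = sorted(cfg.subtype_mix)
    probs = np.array([cfg.subtype_mix[s] for s in subtypes], dtype=float)
    wanted = rng.multinomial(cfg.n_species, probs)
    species: list[TruthSpecies] = []
    for subtype, k in zip(subtypes, wanted):
        pool = pools[subtype]
        if k > len(pool):
            raise ConfigError(
                f"reference hosts only {len(pool)} distinct {subtype} species "
                f"but {k} were requested; enlarge the reference or rebalance "
                f"subtype_mix")
        chosen = rng.choice(len(pool), size=int(k), replace=False)
        species.extend(pool[int(i)] for i in sorted(chosen))

    # log-normal abundances, normalized to a composition
    abund = rng.lognormal(mean=0.0, sigma=1.0, size=len(species))
    abund /= abund.sum()
    for sp, ab in zip(species, abund):
        sp.rel_abundance = float(ab)

    manifest = TruthManifest(species=species, config=cfg)
    _apply_planted_effects(manifest, rng)
    return manifest, refs


def _apply_planted_effects(manifest: TruthManifest, rng: np.random.Generator) -> None:
    """Selectors: an exact tsrna_id, a subtype name, or "random"."""
    unplanted = list(range(len(manifest.species)))
    for selector, lfc in manifest.config.planted_effects:
        lfc = float(lfc)
        if selector == "random":
            if not unplanted:
                raise ConfigError("more planted effects than species")
            j = unplanted.pop(int(rng.integers(len(unplanted))))
            manifest.species[j].log2fc = lfc
            continue
        matched = False
        for j, sp in enumerate(manifest.species):
            if sp.tsrna_id == selector or sp.subtype == selector:
                sp.log2fc = lfc
                matched = True
                if j in unplanted:
                    unplanted.remove(j)
        if not matched:
            raise ConfigError(f"planted-effect selector {selector!r} matched nothing")


def sample_names(cfg: SimConfig) -> list[str]:
    return ([f"Ctrl_{i+1}" for i in range(cfg.n_per_group)]
            + [f"Cd_{i+1}" for i in range(cfg.n_per_group)])


def sample_groups(cfg: SimConfig) -> list[str]:
    return ["Ctrl"] * cfg.n_per_group + ["Cd"] * cfg.n_per_group


def nb_draw(rng: np.random.Generator, mean: np.ndarray,
            dispersion: float) -> np.ndarray:
    """NB with var = mu + dispersion*mu^2; Poisson in the dispersion->0 limit."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(manifest: TruthManifest,
                    cfg: Optional[SimConfig] = None,
                    rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Per-sample NB count matrix for the manifest species."""
    cfg = cfg or manifest.config
    if not manifest.species:
        raise ConfigError("empty truth manifest")
    rng = rng or np.random.default_rng(cfg.rng_seed + 1)
    names = sample_names(cfg)
    means = np.empty((len(manifest.species), len(names)))
    for i, sp in enumerate(manifest.species):
        m_ctrl, m_cd = sp.group_means(cfg.depth)
        means[i] = [m_ctrl] * cfg.n_per_group + [m_cd] * cfg.n_per_group
    counts = nb_draw(rng, means, cfg.nb_dispersion)
    return pd.DataFrame(counts, columns=names, dtype=np.int64,
                        index=pd.Index([sp.tsrna_id for sp in manifest.species],
                                       name="tsrna_id"))


def emit_fastq(manifest: TruthManifest, counts: pd.DataFrame, outdir: str | Path,
               cfg: Optional[SimConfig] = None,
               rng: Optional[np.random.Generator] = None) -> list[Path]:
    """Write one FASTQ per sample: insert + adapter + random pad, read_len bp.

    Substitution errors at ``error_rate`` hit the insert+adapter portion;
    pad bases are uniform random by construction.  Qualities are constant
    'I' (Q40), as no quality-dependent behaviour is modeled.
    """
    cfg = cfg or manifest.config
    rng = rng or np.random.default_rng(cfg.rng_seed + 2)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seq_by_id = {sp.tsrna_id: sp.seq for sp in manifest.species}
    for sp in manifest.species:
        if len(sp.seq) > cfg.read_len:
            raise ConfigError(
                f"{sp.tsrna_id}: fragment ({len(sp.seq)} nt) exceeds read_len")
    qual = "I" * cfg.read_len
    paths = []
    for sample in counts.columns:
        reads: list[str] = []
        for tsrna_id, n in counts[sample].items():
            if n <= 0:
                continue
            template = (seq_by_id[tsrna_id] + cfg.adapter3)[: cfg.read_len]
            pad = cfg.read_len - len(template)
            tarr = np.frombuffer(template.encode(), dtype=np.uint8)
            block = np.tile(tarr, (int(n), 1))
            if cfg.error_rate > 0:
                hits = rng.random(block.shape) < cfg.error_rate
                n_hits = int(hits.sum())
                if n_hits:
                    # substitute with one of the three other bases
                    cur = block[hits]
                    shift = rng.integers(1, 4, size=n_hits)
                    idx = np.searchsorted(_BASES, cur)
                    block[hits] = _BASES[(idx + shift) % 4]
            for r in range(int(n)):
                read = block[r].tobytes().decode()
                if pad:
                    read += _random_seq(rng, pad)
                reads.append(read)
        order = rng.permutation(len(reads))
        path = outdir / f"{sample}.fastq"
        with open(path, "w") as fh:
            for i, j in enumerate(order):
                fh.write(f"@{sample}.{i+1}\n{reads[j]}\n+\n{qual}\n")
        paths.append(path)
    return paths


def simulate_utr_gmt(tsrna_seqs: dict[str, str], n_genes: int = 60,
                     utr_len: int = 300, targets_per_tsrna: int = 6,
                     n_terms: int = 8, rng: Optional[np.random.Generator] = None,
                     ) -> tuple[dict[str, str], dict[str, set[str]]]:
    """Synthetic 3'-UTR database and GMT gene sets for the target stage.

    A subset of genes carries a planted binding site for each tsRNA — the
    perfect reverse complement of the fragment, which yields both a seed
    site and a duplex score well above threshold.  One gene set collects
    the planted targets (so enrichment has signal); the rest are random.
    """
    from .targets import revcomp

    rng = rng or np.random.default_rng(0)
    genes = [f"Gene{i+1:04d}" for i in range(n_genes)]
    utrs = {g: _random_seq(rng, utr_len) for g in genes}
    planted: dict[str, list[str]] = {}
    pool = list(genes)
    for tsrna_id, seq in sorted(tsrna_seqs.items()):
        chosen = list(rng.choice(pool, size=min(targets_per_tsrna, len(pool)),
                                 replace=False))
        planted[tsrna_id] = chosen
        site = revcomp(seq)
        for g in chosen:
            utr = utrs[g]
            pos = int(rng.integers(0, max(1, len(utr) - len(site))))
            utrs[g] = utr[:pos] + site + utr[pos + len(site):]
    all_planted = sorted({g for gs in planted.values() for g in gs})
    gene_sets: dict[str, set[str]] = {"planted_targets": set(all_planted)}
    for t in range(n_terms - 1):
        size = int(rng.integers(5, max(6, n_genes // 3)))
        gene_sets[f"random_set_{t+1}"] = set(
            rng.choice(genes, size=size, replace=False))
    return utrs, gene_sets


def write_gmt(gene_sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[term]))
            fh.write(f"{term}\tsynthetic\t{genes}\n")


def write_manifest(manifest: TruthManifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, sep="\t")


def config_to_dict(cfg: SimConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_from_dict(d: dict) -> SimConfig:
    cfg = SimConfig(**d)
    cfg.validate()
    return cfg
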