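"""Synthetic two-species RNA-seq data with planted, recoverable truth.

Counts are negative binomial with ``Var = mu + phi * mu**2`` and a single
dispersion ``phi`` shared across genes. Per-gene baseline abundances are
log2-normal; species-divergent genes carry a fixed log2 shift in one species,
treatment-responsive genes a multiplicative fold change in the treated
samples of the species dictated by their truth class. Library sizes are drawn
uniformly per sample and enter through the NB mean (no post-hoc thinning), so
the count distribution stays exactly NB.

Sequence generators produce one-to-one ortholog transcript pairs related by
independent per-base substitution, and error-bearing reads whose names encode
their species and transcript of origin.

Reproducibility: one master seed; every generator derives an independent
substream as ``default_rng(SeedSequence(seed, spawn_key=(k,)))`` with a fixed
``k`` per generator (counts 0, treatment 1, transcripts 2, reads 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

from .io_formats import ExpressionTable, OrthologTable, make_record

__all__ = [
    "TwoSpeciesSimConfig",
    "SimTruth",
    "gen_two_species_counts",
    "gen_treatment_experiment",
    "gen_ortholog_transcripts",
    "gen_reads",
    "parse_read_truth",
]

_STREAM = {"counts": 0, "treatment": 1, "transcripts": 2, "reads": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM[stream],)))


@dataclass
class TwoSpeciesSimConfig:
    """Design of a simulated human/mouse ortholog count experiment.

    Defaults mirror a small purified-astrocyte bulk RNA-seq study: a few
    thousand genes, 4-6 biological replicates per group, moderate NB
    overdispersion (phi = 0.1), and ~1e6 reads per library.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 6
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    dispersion: float = 0.1
    frac_divergent: float = 0.1
    divergence_log2_shift: float = 6.0
    frac_responsive: float = 0.1
    response_log2fc: float = 2.0
    conserved_fraction: float = 0.5
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    gene_length_range: tuple[int, int] = (500, 10_000)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_divergent", "frac_responsive", "conserved_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_samples_per_group < 2:
            raise ValueError("need n_samples_per_group >= 2")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid library_size_range")


@dataclass
class SimTruth:
    """Planted per-gene labels, keyed by human gene id.

    ``divergence``: divergent_up_human / divergent_up_mouse / null.
    ``response``: responsive_conserved / responsive_human_only /
    responsive_mouse_only / null; ``response_direction`` is +1 (up), -1
    (down) or 0 for null genes.
    """

    divergence: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    response: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    response_direction: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    def divergent_genes(self) -> set[str]:
        return set(self.divergence.index[self.divergence != "null"])

    def responsive_genes(self, species: str) -> set[str]:
        wanted = {"responsive_conserved", f"responsive_{species}_only"}
        return set(self.response.index[self.response.isin(wanted)])


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _gene_ids(n: int) -> tuple[list[str], list[str]]:
    human = [f"HG{i:05d}" for i in range(n)]
    mouse = [f"mg{i:05d}" for i in range(n)]
    return human, mouse


def _sample_counts(rng, log2_mean: np.ndarray, libs: np.ndarray, phi: float,
                   gene_index, sample_ids) -> pd.DataFrame:
    """NB counts for one species/condition block; log2_mean is gene x sample."""
    q = 2.0 ** log2_mean
    mu = q / q.sum(axis=0, keepdims=True) * libs[np.newaxis, :]
    return pd.DataFrame(_nb_draw(rng, mu, phi), index=gene_index, columns=sample_ids)


def gen_two_species_counts(config: TwoSpeciesSimConfig):
    """Simulate ortholog count matrices with planted species-divergent genes.

    Returns ``(expr_human, expr_mouse, orthologs, lengths, truth)``. Exactly
    ``round(frac_divergent * n_genes)`` genes carry the log2 shift, split
    evenly between a human-up and a mouse-up half.
    """
    cfg = config
    rng = _rng(cfg.seed, "counts")
    hids, mids = _gene_ids(cfg.n_genes)
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)

    n_div = round(cfg.frac_divergent * cfg.n_genes)
    div_genes = rng.choice(cfg.n_genes, size=n_div, replace=False)
    up_human = div_genes[: n_div // 2]
    up_mouse = div_genes[n_div // 2:]
    labels = np.array(["null"] * cfg.n_genes, dtype=object)
    labels[up_human] = "divergent_up_human"
    labels[up_mouse] = "divergent_up_mouse"

    # divergence is a symmetric between-species contrast totalling the full
    # log2 shift: +shift/2 in the higher species, -shift/2 in the other, so a
    # planted gene moves in rank in both species regardless of its baseline
    half = cfg.divergence_log2_shift / 2.0
    shift_h = np.zeros(cfg.n_genes)
    shift_m = np.zeros(cfg.n_genes)
    shift_h[up_human] += half
    shift_m[up_human] -= half
    shift_m[up_mouse] += half
    shift_h[up_mouse] -= half

    n = cfg.n_samples_per_group
    lo, hi = cfg.library_size_range
    tables = {}
    for species, shift, ids in (("human", shift_h, hids), ("mouse", shift_m, mids)):
        libs = rng.integers(lo, hi + 1, size=n).astype(float)
        log2_mean = (baseline + shift)[:, np.newaxis].repeat(n, axis=1)
        samples = [f"{species[0]}s{j}" for j in range(n)]
        values = _sample_counts(rng, log2_mean, libs, cfg.dispersion,
                                pd.Index(ids, name="gene_id"), samples)
        meta = pd.DataFrame({"species": species, "condition": "acute"},
                            index=pd.Index(samples, name="sample_id"))
        tables[species] = ExpressionTable(values.astype(float), meta)

    orthologs = OrthologTable(pd.DataFrame({"human": hids, "mouse": mids}))
    lengths = pd.Series(
        rng.integers(*cfg.gene_length_range, size=cfg.n_genes),
        index=hids, name="length_bp",
    )
    lengths_m = pd.Series(lengths.to_numpy(), index=mids, name="length_bp")
    truth = SimTruth(divergence=pd.Series(labels, index=hids))
    return tables["human"], tables["mouse"], orthologs, pd.concat([lengths, lengths_m]), truth


def gen_treatment_experiment(config: TwoSpeciesSimConfig):
    """Simulate a paired control/treated design in both species.

    ``round(frac_responsive * n_genes)`` genes respond; of those,
    ``round(conserved_fraction * n_responsive)`` respond in both species and
    the remainder are split evenly between human-only and mouse-only
    responders. Within every class, up- and downregulation are split evenly.
    Returns ``(expr_human, expr_mouse, orthologs, lengths, truth)`` where each
    expression table holds ``n_samples_per_group`` control and treated
    samples with ``replicate_pair`` metadata pairing them.
    """
    cfg = config
    rng = _rng(cfg.seed, "treatment")
    hids, mids = _gene_ids(cfg.n_genes)
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)

    n_resp = round(cfg.frac_responsive * cfg.n_genes)
    resp_genes = rng.choice(cfg.n_genes, size=n_resp, replace=False)
    n_cons = round(cfg.conserved_fraction * n_resp)
    conserved = resp_genes[:n_cons]
    rest = resp_genes[n_cons:]
    human_only = rest[: len(rest) // 2]
    mouse_only = rest[len(rest) // 2:]

    labels = np.array(["null"] * cfg.n_genes, dtype=object)
    labels[conserved] = "responsive_conserved"
    labels[human_only] = "responsive_human_only"
    labels[mouse_only] = "responsive_mouse_only"
    direction = np.zeros(cfg.n_genes, dtype=int)
    for cls in (conserved, human_only, mouse_only):
        direction[cls[: len(cls) // 2]] = 1
        direction[cls[len(cls) // 2:]] = -1

    respond_h = np.zeros(cfg.n_genes, dtype=bool)
    respond_m = np.zeros(cfg.n_genes, dtype=bool)
    respond_h[conserved] = respond_h[human_only] = True
    respond_m[conserved] = respond_m[mouse_only] = True

    n = cfg.n_samples_per_group
    lo, hi = cfg.library_size_range
    tables = {}
    for species, respond, ids in (("human", respond_h, hids), ("mouse", respond_m, mids)):
        effect = np.where(respond, direction * cfg.response_log2fc, 0.0)
        samples, conds, pairs, blocks = [], [], [], []
        for cond in ("control", "treated"):
            libs = rng.integers(lo, hi + 1, size=n).astype(float)
            shift = effect if cond == "treated" else np.zeros(cfg.n_genes)
            log2_mean = (baseline + shift)[:, np.newaxis].repeat(n, axis=1)
            ids_cond = [f"{species[0]}_{cond}{j}" for j in range(n)]
            blocks.append(_sample_counts(rng, log2_mean, libs, cfg.dispersion,
                                         pd.Index(ids, name="gene_id"), ids_cond))
            samples += ids_cond
            conds += [cond] * n
            pairs += [f"{species[0]}pair{j}" for j in range(n)]
        values = pd.concat(blocks, axis=1).astype(float)
        meta = pd.DataFrame({"species": species, "condition": conds,
                             "replicate_pair": pairs},
                            index=pd.Index(samples, name="sample_id"))
        tables[species] = ExpressionTable(values, meta)

    orthologs = OrthologTable(pd.DataFrame({"human": hids, "mouse": mids}))
    lengths = pd.Series(rng.integers(*cfg.gene_length_range, size=cfg.n_genes),
                        index=hids, name="length_bp")
    lengths = pd.concat([lengths, pd.Series(lengths.to_numpy(), index=mids,
                                            name="length_bp")])
    truth = SimTruth(response=pd.Series(labels, index=hids),
                     response_direction=pd.Series(direction, index=hids))
    return tables["human"], tables["mouse"], orthologs, lengths, truth


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def gen_ortholog_transcripts(n_pairs: int, length_bp: int, divergence: float,
                             seed: int = 0) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Paired (human-like, mouse-like) transcript sequences.

    The mouse sequence derives from the human one by independent per-base
    substitution with probability ``divergence``, uniform over the three
    alternative bases, so the expected Hamming fraction equals ``divergence``
    exactly (a substitution always changes the base).
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    rng = _rng(seed, "transcripts")
    human, mouse = [], []
    for i in range(n_pairs):
        h = rng.integers(0, 4, size=length_bp)
        hit = rng.random(length_bp) < divergence
        # shift by 1..3 mod 4: uniform over the three other bases
        m = np.where(hit, (h + rng.integers(1, 4, size=length_bp)) % 4, h)
        hseq = b"".join(_BASES[h]).decode()
        mseq = b"".join(_BASES[m]).decode()
        human.append(make_record(f"t{i:04d}", hseq))
        mouse.append(make_record(f"t{i:04d}", mseq))
    return human, mouse


def gen_reads(transcripts: list[SeqRecord], read_length: int, n_reads: int,
              error_rate: float, seed: int = 0, species: str = "human") -> list[SeqRecord]:
    """Uniform-coverage error-bearing reads from a transcript set.

    Start positions are uniform over each chosen transcript; substitution
    errors occur per base at ``error_rate``. The read id encodes the truth as
    ``r<i>|<species>|<transcript id>``.
    """
    if transcripts and read_length > min(len(t.seq) for t in transcripts):
        raise ValueError("read_length exceeds the shortest transcript")
    rng = _rng(seed, "reads")
    reads = []
    n_t = len(transcripts)
    for i in range(n_reads):
        t = transcripts[int(rng.integers(0, n_t))]
        seq = str(t.seq)
        start = int(rng.integers(0, len(seq) - read_length + 1))
        frag = np.frombuffer(seq[start:start + read_length].encode(), dtype="S1")
        codes = np.searchsorted(_BASES, frag)  # _BASES is sorted (A<C<G<T)
        hit = rng.random(read_length) < error_rate
        codes = np.where(hit, (codes + rng.integers(1, 4, size=read_length)) % 4, codes)
        read_seq = b"".join(_BASES[codes]).decode()
        reads.append(make_record(f"r{i}|{species}|{t.id}", read_seq,
                                 qualities=[40] * read_length))
    return reads


def parse_read_truth(read_id: str) -> tuple[str, str]:
    """(species, transcript id) encoded in a simulated read name."""
    _, species, tid = read_id.split("|", 2)
    return species, tid
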