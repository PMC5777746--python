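"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study conditions of a two-platform mouse
microarray re-analysis: an annotation table mixing coding, ``NR_``-only,
biotype-only, dual-evidence, conflicting and short-RNA probe sets; a
probe-level intensity matrix of ≈1300 lncRNA probe sets × ≈18 arrays
(11 probes per set) with planted differentially expressed sets, planted
outlier arrays and planted rank-correlated trans pairs; a genome layout
with coding genes planted inside and outside the 10-kb cis window; and
lncRNA sequences with planted binding-motif consensi.

Every stream of randomness derives from the single config seed through
independent child streams (annotation / experiment / genome / sequences),
so regenerating one component never perturbs another.

The intensity model follows the background-correction convention used
downstream: linear signal (2 to the log2 biological expression, times a
per-probe affinity and a log-normal measurement error) plus additive
Gaussian optical background.  Planted trans pairs share a Gaussian latent
driver whose correlation is the analytic inverse of the target Spearman
coefficient (rho = (6/pi)·asin(r/2)), i.e. a monotone-transform
construction that lands the population rank correlation exactly on
target.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from lncarray import cis as cis_mod
from lncarray.enrichment import PWM, RNA_ALPHABET, write_pwm_file
from lncarray.errors import ValidationError

# child-stream indices off the master seed
_STREAM_ANNOTATION = 0
_STREAM_EXPERIMENT = 1
_STREAM_GENOME = 2
_STREAM_SEQUENCES = 3


@dataclass(frozen=True)
class GenomeConfig:
    """Layout parameters for the synthetic genome."""

    chrom_sizes: tuple[tuple[str, int], ...] = (
        ("chr1", 40_000_000), ("chr2", 40_000_000), ("chr3", 40_000_000),
    )
    n_lncs: int = 12
    n_genes: int = 30
    n_within_window: int = 8
    window: int = 10_000
    lnc_length: tuple[int, int] = (2_000, 60_000)
    gene_length: tuple[int, int] = (1_000, 40_000)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator, with defaults sized to the study
    conditions (≈1300 lncRNA probe sets on ≈18 retained arrays, strongly
    shifted planted effects, one corrupted array)."""

    seed: int = 0
    n_probesets: int = 1300
    probes_per_set: int = 11
    n_case: int = 14
    n_control: int = 4
    fraction_lncrna: float = 0.40
    fraction_conflict: float = 0.05
    fraction_short: float = 0.05
    n_de: int = 40
    de_log2_effect: float = 2.0
    noise_sd: float = 0.25              # log2-scale measurement noise per probe
    n_outlier_arrays: int = 1
    outlier_noise_factor: float = 4.0
    n_trans_pairs: int = 8
    trans_rho_target: float = 0.9
    trans_latent_sd: float = 1.5        # log2 sd of the shared biological driver
    baseline_log2_range: tuple[float, float] = (7.0, 13.0)
    # real arrays carry a large fraction of absent transcripts whose probes
    # read essentially optical background; they anchor the background-peak
    # parameter estimate and dilute the screened universe realistically
    fraction_unexpressed: float = 0.25
    unexpressed_log2_range: tuple[float, float] = (2.0, 4.0)
    optical_mean: float = 40.0
    optical_sd: float = 6.0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    n_sequences: int = 5
    sequence_length: int = 500
    n_pwms: int = 6
    pwm_width: int = 7
    n_planted_motifs: int = 10

    def __post_init__(self) -> None:
        for name in ("n_probesets", "probes_per_set", "n_case", "n_control",
                     "n_de", "n_outlier_arrays", "n_trans_pairs",
                     "n_sequences", "n_pwms", "n_planted_motifs"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("fraction_lncrna", "fraction_conflict", "fraction_short"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.fraction_lncrna + self.fraction_conflict + self.fraction_short > 1:
            raise ValidationError("class fractions must sum to <= 1")
        if self.de_log2_effect < 0:
            raise ValidationError("de_log2_effect must be >= 0")
        if self.pwm_width < 2:
            raise ValidationError("pwm_width must be >= 2")
        if self.sequence_length < self.pwm_width:
            raise ValidationError("sequences must be at least pwm_width long")


@dataclass
class GroundTruth:
    """What was planted, for recovery checks."""

    probe_classes: dict[str, str] = field(default_factory=dict)     # probe -> expected status
    probe_sources: dict[str, str] = field(default_factory=dict)     # lncRNA probes -> source
    probe_genes: dict[str, str] = field(default_factory=dict)       # probe -> gene key
    de_probesets: dict[str, str] = field(default_factory=dict)      # probe set -> up/down
    outlier_arrays: list[str] = field(default_factory=list)
    trans_pairs: list[dict] = field(default_factory=list)           # lnc/gene set + sign
    cis_pairs: list[dict] = field(default_factory=list)             # lnc/gene + relation + gap
    motif_placements: list[dict] = field(default_factory=list)      # seq, protein, offset

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    children = np.random.SeedSequence(cfg.seed).spawn(4)
    return np.random.default_rng(children[stream])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_ANN_CLASSES = ("coding", "lnc_refseq_only", "lnc_ensembl_only", "lnc_both",
                "conflict", "short_rna")
_EXPECTED_STATUS = {
    "coding": "excluded_coding",
    "lnc_refseq_only": "lncRNA",
    "lnc_ensembl_only": "lncRNA",
    "lnc_both": "lncRNA",
    "conflict": "excluded_conflict",
    "short_rna": "excluded_short_or_pseudo",
}
_EXPECTED_SOURCE = {
    "lnc_refseq_only": "refseq_only",
    "lnc_ensembl_only": "ensembl_only",
    "lnc_both": "both",
}
_LNC_BIOTYPES = ("lincRNA", "processed_transcript", "macro_lncRNA", "misc_RNA")
_SHORT_BIOTYPES = ("snoRNA", "snRNA", "miRNA", "rRNA", "tRNA")


def simulate_annotation(
    cfg: SimulationConfig, out_csv: str | Path
) -> GroundTruth:
    """Emit a NetAffx-like annotation CSV with known probe classes.

    lncRNA probes split evenly across the three evidence sources; conflict
    probes carry an NR_ accession together with a protein-coding or
    pseudogene Ensembl biotype.  Several probes may map to one gene so
    that distinct-gene counts fall below probe counts.
    """
    rng = _rng(cfg, _STREAM_ANNOTATION)
    n = cfg.n_probesets
    p_lnc = cfg.fraction_lncrna / 3.0
    probs = np.array([
        1.0 - cfg.fraction_lncrna - cfg.fraction_conflict - cfg.fraction_short,
        p_lnc, p_lnc, p_lnc, cfg.fraction_conflict, cfg.fraction_short,
    ])
    classes = rng.choice(len(_ANN_CLASSES), size=n, p=probs)
    # a gene pool smaller than the probe count induces multi-probe genes
    n_genes = max(1, int(0.7 * n))
    gene_of_probe = rng.integers(0, n_genes, size=n)

    truth = GroundTruth()
    rows = []
    for i in range(n):
        cls = _ANN_CLASSES[classes[i]]
        pid = f"14{i:05d}_at"
        g = int(gene_of_probe[i])
        symbol = f"Gene{g}"
        ens_id = f"ENSMUSG{g:011d}"
        refseq, ensembl, biotype = "---", "---", "---"
        if cls == "coding":
            refseq = f"NM_{100000 + g}"
            ensembl, biotype = ens_id, "protein_coding"
        elif cls == "lnc_refseq_only":
            refseq = f"NR_{100000 + g}"
            symbol = f"Lnc{g}"
        elif cls == "lnc_ensembl_only":
            ensembl = ens_id
            biotype = str(rng.choice(_LNC_BIOTYPES))
            symbol = f"Lnc{g}"
        elif cls == "lnc_both":
            refseq = f"NR_{100000 + g}"
            ensembl = ens_id
            biotype = str(rng.choice(_LNC_BIOTYPES))
            symbol = f"Lnc{g}"
        elif cls == "conflict":
            refseq = f"NR_{100000 + g}"
            ensembl = ens_id
            biotype = str(rng.choice(("protein_coding", "processed_pseudogene")))
            symbol = f"Lnc{g}"
        elif cls == "short_rna":
            ensembl = ens_id
            biotype = str(rng.choice(_SHORT_BIOTYPES))
            symbol = f"Short{g}"
        rows.append({
            "Probe Set ID": pid,
            "Gene Symbol": symbol,
            "Gene Title": f"synthetic {cls} gene {g}",
            "RefSeq Transcript ID": refseq,
            "Ensembl Gene ID": ensembl,
            "Ensembl Biotype": biotype,
        })
        truth.probe_classes[pid] = _EXPECTED_STATUS[cls]
        if cls in _EXPECTED_SOURCE:
            truth.probe_sources[pid] = _EXPECTED_SOURCE[cls]
            truth.probe_genes[pid] = symbol
    pd.DataFrame(rows).to_csv(out_csv, index=False, lineterminator="\n")
    return truth


# ---------------------------------------------------------------------------
# probe-level experiment
# ---------------------------------------------------------------------------

def _spearman_to_pearson(rho_s: float) -> float:
    """Invert rho_s = (6/pi) asin(r/2) for a Gaussian copula."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _sample_spearman(x: np.ndarray, y: np.ndarray) -> float:
    xr = np.argsort(np.argsort(x)).astype(float)
    yr = np.argsort(np.argsort(y)).astype(float)
    return float(np.corrcoef(xr, yr)[0, 1])


def _draw_correlated_pair(
    rng: np.random.Generator, n: int, r_latent: float, rho_target: float,
    margin: float = 0.03, max_tries: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a Gaussian pair whose REALISED sample rank correlation lands on
    the target.

    The copula correlation alone only centres the sampling distribution of
    the sample Spearman coefficient on the target; at the study's sample
    counts that distribution is wide (sd ≈ 0.06 at n = 18).  The planted
    contract is on the emitted data, so draws are rejected until the sample
    coefficient sits within ``margin`` of the target — an interior margin
    tighter than the ±0.05 guarantee, leaving headroom for downstream
    measurement noise.
    """
    a, b = math.sqrt(r_latent), math.sqrt(1.0 - r_latent)
    for _ in range(max_tries):
        z = rng.standard_normal(n)
        x = a * z + b * rng.standard_normal(n)
        y = a * z + b * rng.standard_normal(n)
        rho = _sample_spearman(x, y)
        if abs(rho - rho_target) <= margin:
            return x, y, rho
    raise ValidationError("could not realise the target rank correlation; "
                          "check trans_rho_target against the sample count")


def simulate_experiment(
    cfg: SimulationConfig,
    probe_tsv: str | Path,
    design_tsv: str | Path,
) -> GroundTruth:
    """Emit a probe-level intensity TSV and its design with planted signal.

    Per probe set g and sample j, the log2 biological signal is a baseline
    (uniform over the configured log2 range) plus, for planted DE sets, ±de_log2_effect in the
    case group, plus, for planted trans-pair members, a shared Gaussian
    driver realising the target rank correlation.  The linear intensity is
    2^(signal + probe affinity + N(0, noise_sd)) plus positive Gaussian
    optical background; planted outlier arrays have their log2 noise
    multiplied by outlier_noise_factor.
    """
    if cfg.n_case < 2 or cfg.n_control < 2:
        raise ValidationError("need at least 2 case and 2 control arrays")
    rng = _rng(cfg, _STREAM_EXPERIMENT)
    n_sets, n_probes = cfg.n_probesets, cfg.probes_per_set
    n_samples = cfg.n_case + cfg.n_control
    if n_samples == 0:
        raise ValidationError("no samples requested")
    set_ids = [f"set{g:05d}_at" for g in range(n_sets)]
    sample_ids = [f"case{j:02d}" for j in range(cfg.n_case)] + \
                 [f"ctrl{j:02d}" for j in range(cfg.n_control)]
    groups = ["case"] * cfg.n_case + ["control"] * cfg.n_control
    is_case = np.array([g == "case" for g in groups])

    truth = GroundTruth()

    n_unexpressed = int(round(cfg.fraction_unexpressed * n_sets))
    needed = cfg.n_de + 2 * cfg.n_trans_pairs + n_unexpressed
    if needed > n_sets:
        raise ValidationError("not enough probe sets for the planted structure")
    special = rng.choice(n_sets, size=needed, replace=False)
    de_sets = special[:cfg.n_de]
    trans_sets = special[cfg.n_de:cfg.n_de + 2 * cfg.n_trans_pairs]
    unexpressed = special[cfg.n_de + 2 * cfg.n_trans_pairs:]

    baseline = rng.uniform(*cfg.baseline_log2_range, size=n_sets)
    baseline[unexpressed] = rng.uniform(*cfg.unexpressed_log2_range,
                                        size=n_unexpressed)
    signal = np.tile(baseline[:, None], (1, n_samples))

    de_dir = rng.choice([1.0, -1.0], size=cfg.n_de)
    for g, d in zip(de_sets, de_dir):
        signal[g, is_case] += d * cfg.de_log2_effect
        truth.de_probesets[set_ids[g]] = "up" if d > 0 else "down"

    r_latent = _spearman_to_pearson(cfg.trans_rho_target)
    pair_sign = rng.choice([1.0, -1.0], size=cfg.n_trans_pairs)
    for k in range(cfg.n_trans_pairs):
        gl, gg = trans_sets[2 * k], trans_sets[2 * k + 1]
        x, y, rho = _draw_correlated_pair(rng, n_samples, r_latent,
                                          cfg.trans_rho_target)
        signal[gl, :] += cfg.trans_latent_sd * x
        signal[gg, :] += pair_sign[k] * cfg.trans_latent_sd * y
        truth.trans_pairs.append({
            "lnc_probeset": set_ids[gl],
            "gene_probeset": set_ids[gg],
            "sign": "positive" if pair_sign[k] > 0 else "negative",
            "target_abs_rho": cfg.trans_rho_target,
            "signal_abs_rho": rho,      # realised before measurement noise
        })

    # per-array log2 noise scale; outliers are drawn from the case group so
    # their removal cannot empty the small control group
    noise_scale = np.full(n_samples, cfg.noise_sd)
    if cfg.n_outlier_arrays:
        out_idx = rng.choice(cfg.n_case, size=cfg.n_outlier_arrays, replace=False)
        noise_scale[out_idx] *= cfg.outlier_noise_factor
        truth.outlier_arrays = sorted(sample_ids[i] for i in out_idx)

    affinity = rng.normal(0.0, 0.7, size=(n_sets, n_probes))
    log2_signal = (
        signal[:, None, :]
        + affinity[:, :, None]
        + rng.standard_normal((n_sets, n_probes, n_samples))
        * noise_scale[None, None, :]
    )
    optical = rng.normal(cfg.optical_mean, cfg.optical_sd,
                         size=(n_sets, n_probes, n_samples))
    intensities = np.exp2(log2_signal) + np.clip(optical, 1.0, None)
    intensities = intensities.reshape(n_sets * n_probes, n_samples)

    probe_ids = [f"{set_ids[g]}:p{p:02d}" for g in range(n_sets) for p in range(n_probes)]
    probe_sets = [set_ids[g] for g in range(n_sets) for _ in range(n_probes)]
    frame = pd.DataFrame(intensities, columns=sample_ids)
    frame.insert(0, "probe_set_id", probe_sets)
    frame.insert(0, "probe_id", probe_ids)
    frame.to_csv(probe_tsv, sep="\t", index=False, float_format="%.6f",
                 lineterminator="\n")
    pd.DataFrame({"sample_id": sample_ids, "group": groups}).to_csv(
        design_tsv, sep="\t", index=False, lineterminator="\n"
    )
    return truth


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def simulate_genome(
    cfg: SimulationConfig,
    lnc_tsv: str | Path,
    gene_tsv: str | Path,
) -> GroundTruth:
    """Emit lncRNA and gene interval tables with known cis relations.

    Each lncRNA owns an exclusive genomic slot wide enough that a gene
    planted near it can never qualify for a different lncRNA; genes planted
    "far" sit more than one window beyond every slot, so the qualifying
    pairs are exactly the planted ones.
    """
    g = cfg.genome
    rng = _rng(cfg, _STREAM_GENOME)
    max_lnc = g.lnc_length[1]
    max_gene = g.gene_length[1]
    # slot: far-gene margin | window+gene buffer | lnc | window+gene buffer | far margin
    buffer = g.window + max_gene + 1
    slot = max_lnc + 2 * buffer + 2 * (g.window + max_gene + 1)
    chrom_names = [c for c, _ in g.chrom_sizes]
    slots: list[tuple[str, int]] = []       # (chrom, slot start)
    for chrom, size in g.chrom_sizes:
        k = size // slot
        slots.extend((chrom, 1 + i * slot) for i in range(k))
    if len(slots) < g.n_lncs:
        raise ValidationError("chromosomes too small for the requested lncRNA count")

    truth = GroundTruth()
    lncs: list[cis_mod.GenomicInterval] = []
    lnc_slot: list[tuple[str, int]] = []
    chosen = rng.choice(len(slots), size=g.n_lncs, replace=False)
    for i, si in enumerate(sorted(chosen.tolist())):
        chrom, s0 = slots[si]
        length = int(rng.integers(g.lnc_length[0], g.lnc_length[1] + 1))
        start = s0 + buffer + g.window + max_gene + 1
        lncs.append(cis_mod.GenomicInterval(chrom, start, start + length - 1,
                                            f"lnc{i:03d}"))
        lnc_slot.append((chrom, s0))

    genes: list[cis_mod.GenomicInterval] = []
    if g.n_within_window > g.n_genes:
        raise ValidationError("n_within_window cannot exceed n_genes")
    near_owner = rng.integers(0, g.n_lncs, size=g.n_within_window)
    for j in range(g.n_within_window):
        lnc = lncs[int(near_owner[j])]
        length = int(rng.integers(g.gene_length[0], g.gene_length[1] + 1))
        relation = str(rng.choice(["upstream", "downstream", "overlap"]))
        if relation == "overlap":
            anchor = int(rng.integers(lnc.start, lnc.end + 1))
            start = max(1, anchor - length // 2)
            gap = 0
        elif relation == "upstream":
            gap = int(rng.integers(0, g.window + 1))
            start = lnc.start - gap - length
        else:
            gap = int(rng.integers(0, g.window + 1))
            start = lnc.end + gap + 1
        gene = cis_mod.GenomicInterval(lnc.chrom, start, start + length - 1,
                                       f"gene{j:03d}")
        genes.append(gene)
        checked = cis_mod.classify_relation(lnc, gene, cis_mod.CisConfig(g.window))
        assert checked is not None and checked.relation == relation
        truth.cis_pairs.append({
            "lncrna_name": lnc.name, "gene_name": gene.name,
            "relation": relation, "gap_bp": checked.gap_bp,
        })

    # far genes: in the margin at the front of an occupied slot, always more
    # than one window away from every lncRNA
    n_far = g.n_genes - g.n_within_window
    far_slots = rng.integers(0, g.n_lncs, size=n_far)
    for j in range(n_far):
        chrom, s0 = lnc_slot[int(far_slots[j])]
        length = int(rng.integers(g.gene_length[0], min(max_gene, buffer - g.window - 2) + 1))
        start = s0 + int(rng.integers(0, buffer - g.window - length - 1))
        genes.append(cis_mod.GenomicInterval(chrom, start, start + length - 1,
                                             f"gene{g.n_within_window + j:03d}"))

    cis_mod.write_interval_tsv(lncs, lnc_tsv)
    cis_mod.write_interval_tsv(genes, gene_tsv)
    return truth


# ---------------------------------------------------------------------------
# sequences and PWMs
# ---------------------------------------------------------------------------

def simulate_sequences_pwms(
    cfg: SimulationConfig,
    fasta_path: str | Path,
    pwm_path: str | Path,
) -> GroundTruth:
    """Emit lncRNA-like RNA sequences and binding-motif matrices.

    Matrices are sharply peaked count matrices (85% consensus letter per
    position); each planted placement embeds a matrix's consensus at a
    recorded 1-based offset of a uniform-background sequence, so a scan at
    threshold 0.8 must recover every placement.
    """
    rng = _rng(cfg, _STREAM_SEQUENCES)
    letters = np.array(list(RNA_ALPHABET))

    pwms: list[PWM] = []
    for m in range(cfg.n_pwms):
        consensus = rng.integers(0, 4, size=cfg.pwm_width)
        counts = np.full((cfg.pwm_width, 4), 5.0)
        counts[np.arange(cfg.pwm_width), consensus] = 85.0
        pwms.append(PWM.from_counts(f"RBP{m:02d}", counts))

    seqs: list[tuple[str, str]] = []
    truth = GroundTruth()
    seq_chars = rng.integers(0, 4, size=(cfg.n_sequences, cfg.sequence_length))
    occupied: dict[int, list[tuple[int, int]]] = {s: [] for s in range(cfg.n_sequences)}
    for placement in range(cfg.n_planted_motifs):
        s = int(rng.integers(0, cfg.n_sequences))
        m = int(rng.integers(0, cfg.n_pwms))
        # keep placements disjoint so none is overwritten by a later one
        for _try in range(200):
            offset = int(rng.integers(0, cfg.sequence_length - cfg.pwm_width + 1))
            span = (offset, offset + cfg.pwm_width)
            if all(span[1] <= a or span[0] >= b for a, b in occupied[s]):
                break
        else:
            raise ValidationError("could not place motifs without overlap; "
                                  "reduce n_planted_motifs or lengthen sequences")
        occupied[s].append(span)
        consensus_codes = pwms[m].weights.argmax(axis=1)
        seq_chars[s, offset:offset + cfg.pwm_width] = consensus_codes
        truth.motif_placements.append({
            "sequence_name": f"lncseq{s:02d}",
            "protein_name": pwms[m].protein_name,
            "offset": offset + 1,
        })
    for s in range(cfg.n_sequences):
        seqs.append((f"lncseq{s:02d}", "".join(letters[seq_chars[s]])))

    with open(fasta_path, "w") as fh:
        for name, seq in seqs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    write_pwm_file(pwms, pwm_path)
    return truth


def simulate_gene_sets(
    universe: Sequence[str],
    path: str | Path,
    seed: int = 0,
    n_sets: int = 20,
    set_size: tuple[int, int] = (5, 30),
) -> None:
    """Write a GMT of random gene sets drawn from ``universe``.

    A convenience for end-to-end runs on synthetic data, where no curated
    ontology exists for the generated gene name space.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(universe)
    if not universe:
        raise ValidationError("gene universe is empty")
    lines = []
    for t in range(n_sets):
        size = int(rng.integers(set_size[0], min(set_size[1], len(universe)) + 1))
        members = rng.choice(universe, size=size, replace=False)
        lines.append("\t".join([f"TERM{t:04d}", f"synthetic term {t}", *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_all(cfg: SimulationConfig, outdir: str | Path) -> dict[str, GroundTruth]:
    """Generate every input file under ``outdir``; returns the truths and
    writes them as JSON alongside the data."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truths = {
        "annotation": simulate_annotation(cfg, outdir / "annotation.csv"),
        "experiment": simulate_experiment(cfg, outdir / "probes.tsv",
                                          outdir / "design.tsv"),
        "genome": simulate_genome(cfg, outdir / "lncrnas.tsv", outdir / "genes.tsv"),
        "sequences": simulate_sequences_pwms(cfg, outdir / "lncrnas.fasta",
                                             outdir / "pwms.txt"),
    }
    for name, truth in truths.items():
        truth.write_json(outdir / f"truth_{name}.json")
    return truths
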