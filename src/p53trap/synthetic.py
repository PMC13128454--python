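"""Seeded generators emulating the data shapes the analysis modules consume.

Each generator draws from ``numpy.random.default_rng(seed)`` (PCG64), whose
integer stream is platform-stable, so identical seed + config produce
identical outputs everywhere.  The emulated structures:

* dependency matrices — cell-line panel Chronos scores: per-gene baseline
  essentiality around -0.3, per-sample noise, optionally a planted
  synthetic-lethal gene shifted in the mutant group;
* proteomics matrices — per-feature z-scored abundance with a planted
  "p53-like" protein elevated in missense-mutant samples;
* nomination tables — gene essentiality + protein concentration (nM) with
  planted scarce-and-essential targets among decoys;
* read pairs — paired-end alignments to a synthetic transcript carrying two
  heterozygous variants in a known cis or trans configuration, with
  sequencing errors;
* dose-response tables — 4PL curves with replicate noise.

Sample-size defaults (200 WT / 50 missense / 20 truncating) mirror the
mutant/WT imbalance of large cancer cell-line panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .screen import SampleAnnotation, ScoreMatrix
from .phasing import VariantSite

PLANT_GROUPS = ("missense", "truncating", "mutant", "WT")


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared knobs for the matrix generators.

    ``planted_effects`` lists (feature_index, group, shift) triples; for the
    proteomics generator the shift is the TARGET separation in z-units after
    per-feature standardization (the raw shift is back-computed so the
    requested z-separation is realized in expectation).
    """

    seed: int = 0
    n_samples_wt: int = 200
    n_samples_missense: int = 50
    n_samples_truncating: int = 20
    n_features: int = 2000
    planted_effects: tuple = ()
    noise_sd: float = 0.3
    error_rate: float = 0.01
    dose_grid: tuple = tuple(np.geomspace(1e-9, 1e-5, 8))

    def __post_init__(self) -> None:
        for name in ("n_samples_wt", "n_samples_missense", "n_samples_truncating",
                     "n_features"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")
        for feat, group, _ in self.planted_effects:
            if group not in PLANT_GROUPS:
                raise ValueError(f"planted group must be in {PLANT_GROUPS}, got {group!r}")
            if not 0 <= feat < self.n_features:
                raise ValueError(f"planted feature index {feat} out of range")


def _annotation(config: GeneratorConfig) -> SampleAnnotation:
    status = (
        ["WT"] * config.n_samples_wt
        + ["missense"] * config.n_samples_missense
        + ["truncating"] * config.n_samples_truncating
    )
    ids = [f"S{i:04d}" for i in range(len(status))]
    return SampleAnnotation(pd.DataFrame({"sample_id": ids, "tp53_status": status}))


def _group_mask(annotation: SampleAnnotation, group: str) -> np.ndarray:
    status = annotation.table["tp53_status"].to_numpy()
    if group == "mutant":
        return status != "WT"
    return status == group


def gen_dependency_matrix(
    config: GeneratorConfig,
) -> tuple[ScoreMatrix, SampleAnnotation]:
    """Null Chronos-like matrix, with optional planted differential dependencies.

    Per-gene baseline means ~ Normal(-0.3, 0.3) are shared by all samples;
    per-sample noise ~ Normal(0, noise_sd).  A planted effect (g, group, s)
    adds ``s`` to gene ``g`` in the given sample group — e.g. shift -0.6 on
    the mutant group emulates a synthetic-lethal interaction.
    """
    rng = np.random.default_rng(config.seed)
    annotation = _annotation(config)
    n_samples = len(annotation.table)
    baseline = rng.normal(-0.3, 0.3, size=config.n_features)
    values = baseline[None, :] + rng.normal(0.0, config.noise_sd,
                                            size=(n_samples, config.n_features))
    for feat, group, shift in config.planted_effects:
        values[_group_mask(annotation, group), feat] += shift
    df = pd.DataFrame(
        values,
        index=annotation.table["sample_id"],
        columns=[f"GENE{i:05d}" for i in range(config.n_features)],
    )
    return ScoreMatrix(df, "dependency"), annotation


def gen_proteomics_matrix(
    config: GeneratorConfig,
) -> tuple[ScoreMatrix, SampleAnnotation]:
    """z-scored proteomics matrix with planted group separations.

    Raw abundance is unit-normal noise (times ``noise_sd``); planted shifts
    are specified in z-units AFTER per-feature standardization.  Because
    standardizing divides by the pooled SD — which a planted shift inflates
    by sqrt(1 + f(1-f) (s/noise_sd)^2) for group fraction f — the raw shift
    is back-computed so the realized z-separation matches the request.
    Requested z-shifts must satisfy d^2 f(1-f) < 1 (separation achievable
    after standardization).
    """
    rng = np.random.default_rng(config.seed)
    annotation = _annotation(config)
    n_samples = len(annotation.table)
    values = rng.normal(0.0, config.noise_sd, size=(n_samples, config.n_features))
    for feat, group, z_shift in config.planted_effects:
        mask = _group_mask(annotation, group)
        f = mask.mean()
        denom = 1.0 - z_shift**2 * f * (1.0 - f)
        if denom <= 0:
            raise ValueError(
                f"z-shift {z_shift} with group fraction {f:.3f} is not achievable "
                "after per-feature standardization"
            )
        raw_shift = z_shift * config.noise_sd / np.sqrt(denom)
        values[mask, feat] += raw_shift
    # per-feature z-scoring (population SD), as the consuming screen expects
    values = (values - values.mean(axis=0)) / values.std(axis=0)
    df = pd.DataFrame(
        values,
        index=annotation.table["sample_id"],
        columns=[f"PROT{i:05d}" for i in range(config.n_features)],
    )
    return ScoreMatrix(df, "abundance_z"), annotation


def gen_nomination_tables(
    config: GeneratorConfig,
    n_planted: int = 5,
    planted_chronos: tuple = (-3.0, -2.5),
    planted_abundance_nM: tuple = (5.0, 50.0),
) -> tuple[pd.Series, pd.Series, list]:
    """Essentiality and abundance tables with planted nominatable targets.

    Decoy genes draw mean Chronos ~ Normal(-0.3, 0.4) — mean scores at or
    below -2 are rare, as in real panels — and abundance ~ 10^Normal(2, 1)
    nM (median 100 nM).  ``n_planted`` genes draw Chronos and abundance
    uniformly from the given strongly-essential, scarce ranges.  Returns
    (essentiality, abundance, planted_gene_ids).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_features
    if n_planted > n:
        raise ValueError("n_planted exceeds n_features")
    genes = [f"GENE{i:05d}" for i in range(n)]
    chronos = rng.normal(-0.3, 0.4, size=n)
    abundance = 10.0 ** rng.normal(2.0, 1.0, size=n)
    planted = list(rng.choice(n, size=n_planted, replace=False))
    for i in planted:
        chronos[i] = rng.uniform(*planted_chronos)
        abundance[i] = rng.uniform(*planted_abundance_nM)
    ess = pd.Series(chronos, index=genes, name="mean_chronos")
    ab = pd.Series(abundance, index=genes, name="abundance_nM")
    return ess, ab, sorted(genes[i] for i in planted)


# ---------------------------------------------------------------------------
# read-pair generator

TRANSCRIPT_NAME = "TX1"
TRANSCRIPT_LEN = 300
SITE1 = VariantSite(position=100, ref_base="A", alt_base="G")
SITE2 = VariantSite(position=180, ref_base="C", alt_base="T")
READ_LEN = 80
BASE_QUAL = 37


def _transcript_sequence(rng: np.random.Generator) -> str:
    seq = rng.choice(list("ACGT"), size=TRANSCRIPT_LEN)
    seq[SITE1.position - 1] = SITE1.ref_base
    seq[SITE2.position - 1] = SITE2.ref_base
    return "".join(seq)


@dataclass
class ReadPairDataset:
    """Synthetic paired alignments plus their per-pair ground truth."""

    reads: list  # pysam.AlignedSegment, paired
    truth: pd.DataFrame  # pair_id, haplotype, allele_site1, allele_site2
    phase: str
    sites: tuple = (SITE1, SITE2)
    header: pysam.AlignmentHeader = field(
        default_factory=lambda: pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "unsorted"},
                "SQ": [{"SN": TRANSCRIPT_NAME, "LN": TRANSCRIPT_LEN}],
            }
        )
    )

    def write_sam(self, path) -> None:
        with pysam.AlignmentFile(str(path), "wh", header=self.header) as fh:
            for read in self.reads:
                fh.write(read)


def gen_read_pairs(
    phase: str,
    n_pairs: int = 100,
    error_rate: float = 0.01,
    seed: int = 0,
) -> ReadPairDataset:
    """Paired reads from a heterozygous two-haplotype transcript model.

    ``phase='cis'`` puts both alternate alleles on haplotype 1 (haplotype 2
    all-reference); ``'trans'`` puts one alternate allele on each.  Each
    pair picks a haplotype with probability 1/2; mate 1 covers site 1 and
    mate 2 covers site 2; each base miscalls to a uniformly random other
    nucleotide with probability ``error_rate``.  The truth table records the
    haplotype and the allele category of the base ACTUALLY emitted at each
    site (so extraction must round-trip it exactly).
    """
    if phase not in ("cis", "trans"):
        raise ValueError("phase must be 'cis' or 'trans'")
    rng = np.random.default_rng(seed)
    ref = _transcript_sequence(rng)
    hap1 = {SITE1.position: SITE1.alt_base,
            SITE2.position: SITE2.alt_base if phase == "cis" else SITE2.ref_base}
    hap2 = {SITE1.position: SITE1.ref_base,
            SITE2.position: SITE2.ref_base if phase == "cis" else SITE2.alt_base}
    haplotypes = (hap1, hap2)
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"},
         "SQ": [{"SN": TRANSCRIPT_NAME, "LN": TRANSCRIPT_LEN}]}
    )
    others = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}

    reads, truth_rows = [], []
    for i in range(n_pairs):
        hap_idx = int(rng.integers(2))
        hap = haplotypes[hap_idx]
        pair_id = f"pair{i:05d}"
        # mate start positions jittered but guaranteed to cover their site
        start1 = int(rng.integers(max(0, SITE1.position - READ_LEN), SITE1.position))
        start2 = int(
            rng.integers(
                max(0, SITE2.position - READ_LEN),
                min(SITE2.position, TRANSCRIPT_LEN - READ_LEN + 1),
            )
        )
        emitted = {}
        for mate_idx, start in enumerate((start1, start2)):
            bases = []
            for off in range(READ_LEN):
                pos1 = start + off + 1  # 1-based
                base = hap.get(pos1, ref[pos1 - 1])
                if rng.random() < error_rate:
                    base = others[base][int(rng.integers(3))]
                bases.append(base)
                if pos1 in (SITE1.position, SITE2.position):
                    emitted.setdefault(pos1, []).append(base)
            read = pysam.AlignedSegment(header)
            read.query_name = pair_id
            read.query_sequence = "".join(bases)
            read.reference_id = 0
            read.reference_start = start
            read.cigarstring = f"{READ_LEN}M"
            read.mapping_quality = 60
            read.query_qualities = pysam.qualitystring_to_array(
                chr(BASE_QUAL + 33) * READ_LEN
            )
            read.flag = 0x1 | 0x2 | (0x40 if mate_idx == 0 else 0x80) | (
                0x20 if mate_idx == 0 else 0x10
            )
            read.next_reference_id = 0
            read.next_reference_start = start2 if mate_idx == 0 else start1
            reads.append(read)

        def allele(site: VariantSite) -> str:
            calls = emitted.get(site.position, [])
            if not calls:
                return "uncovered"
            if len(set(calls)) > 1:
                return "other"
            return site.classify(calls[0])

        truth_rows.append(
            {
                "pair_id": pair_id,
                "haplotype": hap_idx + 1,
                "allele_site1": allele(SITE1),
                "allele_site2": allele(SITE2),
            }
        )
    truth = pd.DataFrame(truth_rows)
    return ReadPairDataset(reads=reads, truth=truth, phase=phase, header=header)


def gen_dose_response(
    ec50: float = 25e-9,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    noise_sd: float = 0.0,
    dose_grid: Sequence[float] = tuple(np.geomspace(1e-9, 1e-5, 8)),
    n_rep: int = 3,
    seed: int = 0,
    readout_kind: str = "competition_fraction",
    n_vehicle: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """4PL observations with Gaussian replicate noise, plus the truth dict.

    Vehicle (dose 0) rows are generated at the zero-dose limit of the curve
    (``top`` for hill > 0).  Returns (table, truth).
    """
    from .doseresponse import four_pl

    rng = np.random.default_rng(seed)
    rows = []
    vehicle_level = top if hill > 0 else bottom
    for _ in range(n_vehicle):
        rows.append({"dose": 0.0, "response": vehicle_level})
    for dose in dose_grid:
        y = four_pl(dose, ec50, hill, top, bottom)
        for _ in range(n_rep):
            rows.append({"dose": float(dose), "response": float(y)})
    table = pd.DataFrame(rows)
    table["replicate"] = table.groupby("dose").cumcount()
    if noise_sd > 0:
        table["response"] += rng.normal(0.0, noise_sd, size=len(table))
    table["readout_kind"] = readout_kind
    truth = {"ec50": ec50, "hill": hill, "top": top, "bottom": bottom,
             "noise_sd": noise_sd}
    return table, truth
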