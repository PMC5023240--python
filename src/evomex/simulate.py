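"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study's raw data at desk scale:

* :func:`simulate_expression` — a log2 expression matrix over groups WT, EM
  and one or more evolved lineages, where each gene carries a known
  reaction-norm category (novel / restored / unrestored / reinforced /
  unchanged) realised as additive acclimation (alpha) and adaptation
  (epsilon) effects on the log2 scale with i.i.d. Gaussian replicate noise;
* :func:`simulate_mutations` — multi-type mutation lists over a toy
  annotated genome, optionally with planted ancestral contaminants shared by
  all lineages and an IS-pair-bounded deletion;
* :func:`simulate_growth_curve` — lag / exponential / saturation OD600
  curves with multiplicative noise.

All generators are deterministic given their seed; group means of the
noiseless expression signal equal the configured effects exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .growth import GrowthCurve
from .io import ExpressionMatrix, Feature, GenomeAnnotation, MutationRecord

CATEGORIES = ("novel", "restored", "unrestored", "reinforced", "unchanged")

DEFAULT_PROPORTIONS = {
    "novel": 0.05,
    "restored": 0.10,
    "unrestored": 0.05,
    "reinforced": 0.03,
    "unchanged": 0.77,
}


@dataclass
class SimulationConfig:
    """Configuration for the expression-matrix generator.

    Effects are additive on the log2 scale. ``acclimation_effect`` is the
    magnitude |alpha| of the EM-vs-WT shift for affected genes and
    ``adaptation_effect`` the magnitude |epsilon| of the EVO-vs-EM shift for
    novel/reinforced genes (restored genes reverse alpha instead). Signs are
    drawn at random per gene. ``n_replicates`` defaults to 3 per group, a
    typical microarray design.
    """

    n_genes: int = 2000
    n_probes_per_gene: int = 1
    n_replicates: int = 3
    lineages: tuple[str, ...] = ("F1",)
    category_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    acclimation_effect: float = 2.0
    adaptation_effect: float = 2.0
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    partial_restoration_fraction: float = 0.0
    partial_restoration_c: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_probes_per_gene <= 0 or self.n_replicates <= 0:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        unknown = set(self.category_proportions) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category proportions sum to {total}, not 1")
        if any(v < 0 for v in self.category_proportions.values()):
            raise ValueError("proportions must be non-negative")
        needs_alpha = ("restored", "unrestored", "reinforced")
        needs_epsilon = ("novel", "reinforced")
        if self.acclimation_effect == 0 and any(
            self.category_proportions.get(c, 0) > 0 for c in needs_alpha
        ):
            raise ValueError("acclimation_effect must be nonzero for alpha-affected categories")
        if self.adaptation_effect == 0 and any(
            self.category_proportions.get(c, 0) > 0 for c in needs_epsilon
        ):
            raise ValueError("adaptation_effect must be nonzero for epsilon-affected categories")
        if not 0 <= self.partial_restoration_fraction <= 1:
            raise ValueError("partial_restoration_fraction must lie in [0, 1]")
        if not 0 < self.partial_restoration_c < 1:
            raise ValueError("partial_restoration_c must lie in (0, 1)")

    @property
    def groups(self) -> list[str]:
        return ["WT", "EM"] + [f"EVO_{l}" for l in self.lineages]


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a probe x sample matrix plus its truth table.

    The truth table has one row per gene per lineage with columns locus,
    lineage, category, alpha, epsilon. Category rules: novel genes have
    alpha = 0 and epsilon != 0; restored genes epsilon = -alpha (or -c*alpha
    for the configured partial-restoration fraction); unrestored genes
    epsilon = 0; reinforced genes epsilon shares the sign of alpha.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    cats = rng.choice(
        list(config.category_proportions),
        size=n,
        p=list(config.category_proportions.values()),
    )
    signs = rng.choice([-1.0, 1.0], size=n)
    eps_signs = rng.choice([-1.0, 1.0], size=n)
    partial = rng.random(n) < config.partial_restoration_fraction

    alpha = np.zeros(n)
    epsilon = np.zeros(n)
    for i, cat in enumerate(cats):
        if cat == "novel":
            epsilon[i] = eps_signs[i] * config.adaptation_effect
        elif cat == "restored":
            alpha[i] = signs[i] * config.acclimation_effect
            c = config.partial_restoration_c if partial[i] else 1.0
            epsilon[i] = -c * alpha[i]
        elif cat == "unrestored":
            alpha[i] = signs[i] * config.acclimation_effect
        elif cat == "reinforced":
            alpha[i] = signs[i] * config.acclimation_effect
            epsilon[i] = signs[i] * config.adaptation_effect

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    loci = [f"locus_{i:05d}" for i in range(n)]
    probes = [
        f"g{i:05d}_p{j}" for i in range(n) for j in range(config.n_probes_per_gene)
    ]
    probe_map = pd.Series(
        [loci[i] for i in range(n) for _ in range(config.n_probes_per_gene)],
        index=pd.Index(probes, name="probe"),
        name="locus",
    )

    samples: list[str] = []
    sheet_rows: list[dict] = []
    signal_cols: list[np.ndarray] = []
    gene_signal = {
        "WT": baseline,
        "EM": baseline + alpha,
    }
    for lineage in config.lineages:
        gene_signal[f"EVO_{lineage}"] = baseline + alpha + epsilon
    for group in config.groups:
        lineage = group[4:] if group.startswith("EVO_") else ""
        for r in range(1, config.n_replicates + 1):
            sample = f"{group}_{r}"
            samples.append(sample)
            sheet_rows.append({"sample": sample, "group": group, "lineage": lineage})
            signal_cols.append(np.repeat(gene_signal[group], config.n_probes_per_gene))

    signal = np.column_stack(signal_cols)
    noise = rng.normal(0.0, config.noise_sd, size=signal.shape) if config.noise_sd else 0.0
    values = pd.DataFrame(signal + noise, index=pd.Index(probes, name="probe"), columns=samples)
    sheet = pd.DataFrame(sheet_rows).set_index("sample")
    matrix = ExpressionMatrix(values=values, samples=sheet, probe_map=probe_map)

    truth_rows = []
    for lineage in config.lineages:
        for i in range(n):
            truth_rows.append(
                {
                    "locus": loci[i],
                    "lineage": lineage,
                    "category": cats[i],
                    "alpha": alpha[i],
                    "epsilon": epsilon[i],
                }
            )
    truth = pd.DataFrame(truth_rows)
    return matrix, truth


# ---------------------------------------------------------------------------
# Toy genome and mutation lists
# ---------------------------------------------------------------------------

def simulate_toy_genome(
    seed: int = 0,
    n_genes: int = 20,
    gene_length: int = 900,
    spacing: int = 1100,
    n_is_copies: int = 2,
    is_length: int = 1200,
    is_family: str = "ISMex25",
    seqid: str = "chr1",
    with_sequence: bool = True,
) -> GenomeAnnotation:
    """A single-replicon annotation with evenly spaced CDSs and IS copies.

    Genes are named gene_001.. and laid out head to tail on the + strand;
    IS copies (same family, + orientation) are appended after the genes.
    Sequences are random with genes made of complete codons, so coding-effect
    annotation can translate them.
    """
    rng = np.random.default_rng(seed)
    features: list[Feature] = []
    pos = spacing
    for i in range(1, n_genes + 1):
        features.append(
            Feature(
                feature_id=f"gene_{i:03d}",
                type="CDS",
                seqid=seqid,
                start=pos,
                end=pos + gene_length,
                strand="+",
                locus_tag=f"gene_{i:03d}",
                attributes={"ID": f"gene_{i:03d}", "locus_tag": f"gene_{i:03d}"},
            )
        )
        pos += gene_length + spacing
    for j in range(1, n_is_copies + 1):
        features.append(
            Feature(
                feature_id=f"IS_{j:02d}",
                type="mobile_genetic_element",
                seqid=seqid,
                start=pos,
                end=pos + is_length,
                strand="+",
                locus_tag=f"IS_{j:02d}",
                attributes={"ID": f"IS_{j:02d}", "family": is_family},
            )
        )
        pos += is_length + spacing
    length = pos + spacing
    sequences = None
    if with_sequence:
        seq = rng.choice(list("ACGT"), size=length)
        codons = ("GCT", "TGC", "GAT", "GAA", "TTT", "GGT", "CAT", "ATT", "AAA", "CTG")
        for feat in features:
            if feat.type != "CDS":
                continue
            body = "ATG" + "".join(
                rng.choice(codons) for _ in range(feat.length // 3 - 2)
            ) + "TAA"
            seq[feat.start : feat.end] = list(body)
        sequences = {seqid: "".join(seq)}
    return GenomeAnnotation(
        regions={seqid: length}, features=features, sequences=sequences
    )


@dataclass
class MutationSimConfig:
    """Configuration for the mutation-list generator."""

    lineages: tuple[str, ...] = tuple(f"F{i}" for i in range(1, 9))
    n_mutations_per_lineage: int = 8
    n_ancestral: int = 0
    is_deletion_span: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mutations_per_lineage < 0 or self.n_ancestral < 0:
            raise ValueError("counts must be non-negative")
        if not self.lineages:
            raise ValueError("need at least one lineage")


def simulate_mutations(
    config: MutationSimConfig,
    annotation: GenomeAnnotation | None = None,
) -> tuple[list[MutationRecord], dict]:
    """Generate per-lineage mutation records over a toy genome.

    Returns ``(records, truth)`` where ``truth`` holds the annotation, the
    planted ancestral allele keys and, when requested, the IS-deletion
    interval. Mutation types cycle through SNP, INS, DEL, SUB, MOB, AMP so
    all types appear once enough mutations are requested. Ancestral
    contaminants are identical alleles planted in every lineage. When
    ``is_deletion_span`` is set, two same-family, same-orientation IS copies
    are placed that many bp apart and a DEL bounded by them is emitted in
    the first lineage.
    """
    rng = np.random.default_rng(config.seed)
    if annotation is None:
        annotation = simulate_toy_genome(seed=config.seed, with_sequence=True)
    seqid = next(iter(annotation.regions))
    length = annotation.regions[seqid]
    types = ("SNP", "INS", "DEL", "SUB", "MOB", "AMP")
    records: list[MutationRecord] = []
    rec_id = 0

    def _make(etype: str, position: int, lineage: str) -> MutationRecord:
        nonlocal rec_id
        rec_id += 1
        if not annotation.contains_position(seqid, position):
            raise ValueError(f"position {position} outside toy genome (length {length})")
        base_kwargs = dict(
            record_id=str(rec_id), seqid=seqid, position=position, lineage=lineage
        )
        if etype == "SNP":
            ref = annotation.sequences[seqid][position] if annotation.sequences else "A"
            alt = rng.choice([b for b in "ACGT" if b != ref])
            return MutationRecord(type="SNP", new_seq=str(alt), **base_kwargs)
        if etype == "INS":
            return MutationRecord(
                type="INS", new_seq="".join(rng.choice(list("ACGT"), size=4)), **base_kwargs
            )
        if etype == "DEL":
            return MutationRecord(type="DEL", size=int(rng.integers(1, 30)), **base_kwargs)
        if etype == "SUB":
            return MutationRecord(
                type="SUB",
                size=int(rng.integers(2, 12)),
                new_seq="".join(rng.choice(list("ACGT"), size=3)),
                **base_kwargs,
            )
        if etype == "MOB":
            return MutationRecord(
                type="MOB",
                repeat_name="ISMex25",
                strand=int(rng.choice([-1, 1])),
                duplication_size=3,
                **base_kwargs,
            )
        return MutationRecord(
            type="AMP", size=int(rng.integers(1, 50)) * 3, new_copy_number=2, **base_kwargs
        )

    for lineage in config.lineages:
        for k in range(config.n_mutations_per_lineage):
            etype = types[k % len(types)]
            position = int(rng.integers(0, length - 100))
            records.append(_make(etype, position, lineage))

    ancestral_keys = []
    for k in range(config.n_ancestral):
        position = int(rng.integers(0, length - 100))
        ref = annotation.sequences[seqid][position] if annotation.sequences else "A"
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        for lineage in config.lineages:
            rec_id += 1
            records.append(
                MutationRecord(
                    type="SNP",
                    record_id=str(rec_id),
                    seqid=seqid,
                    position=position,
                    new_seq=alt,
                    lineage=lineage,
                )
            )
        ancestral_keys.append(records[-1].allele_key())

    truth: dict = {"annotation": annotation, "ancestral": ancestral_keys}
    if config.is_deletion_span is not None:
        span = config.is_deletion_span
        is_len = 1200
        start = length
        extra = span + 2 * is_len + 2000
        new_length = length + extra
        annotation.regions[seqid] = new_length
        if annotation.sequences is not None:
            pad = "".join(rng.choice(list("ACGT"), size=extra))
            annotation.sequences[seqid] = annotation.sequences[seqid] + pad
        is_a = Feature(
            feature_id="ISDEL_A",
            type="mobile_genetic_element",
            seqid=seqid,
            start=start,
            end=start + is_len,
            strand="+",
            attributes={"ID": "ISDEL_A", "family": "ISMex25"},
        )
        is_b = Feature(
            feature_id="ISDEL_B",
            type="mobile_genetic_element",
            seqid=seqid,
            start=start + span,
            end=start + span + is_len,
            strand="+",
            attributes={"ID": "ISDEL_B", "family": "ISMex25"},
        )
        annotation.features.extend([is_a, is_b])
        rec_id += 1
        records.append(
            MutationRecord(
                type="DEL",
                record_id=str(rec_id),
                seqid=seqid,
                position=start,
                size=span,
                lineage=config.lineages[0],
            )
        )
        truth["is_deletion"] = (start, start + span)
    return records, truth


# ---------------------------------------------------------------------------
# Growth curves and halos
# ---------------------------------------------------------------------------

def simulate_growth_curve(
    mu: float,
    lag: float,
    od0: float,
    od_max: float,
    noise_cv: float,
    times: Sequence[float],
    seed: int = 0,
    culture_id: str = "well_1",
    strain: str = "",
    condition: str = "",
) -> GrowthCurve:
    """Lag / exponential / saturating OD600 curve with multiplicative noise.

    The deterministic backbone is flat at ``od0`` until ``lag`` hours, then a
    logistic approach to ``od_max`` with maximum specific rate ``mu``
    (``od_max = inf`` gives a pure exponential). Noise is lognormal with the
    stated coefficient of variation, mean-one, applied multiplicatively.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if od0 <= 0:
        raise ValueError("od0 must be positive")
    if od_max <= od0:
        raise ValueError("od_max must exceed od0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    shifted = np.maximum(t - lag, 0.0)
    if np.isinf(od_max):
        od = od0 * np.exp(mu * shifted)
    else:
        od = od_max / (1.0 + (od_max / od0 - 1.0) * np.exp(-mu * shifted))
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        od = od * rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=od.shape)
    return GrowthCurve(
        culture_id=culture_id, times=t, od600=od, strain=strain, condition=condition
    )


def simulate_halo_table(
    protection: Mapping[str, float],
    ancestor_map: Mapping[str, str],
    ancestor_diameter_cm: float = 4.0,
    noise_sd_cm: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Triplicate inhibition-halo diameters with known per-strain protection.

    Each strain's true diameter is ``(1 - protection) * ancestor diameter``;
    ancestors themselves get the base diameter. Gaussian measurement noise is
    added per replicate plate.
    """
    rng = np.random.default_rng(seed)
    rows = []
    strains: dict[str, float] = {}
    for ancestor in set(ancestor_map.values()):
        strains[ancestor] = ancestor_diameter_cm
    for strain, prot in protection.items():
        strains[strain] = (1.0 - prot) * ancestor_diameter_cm
    for strain, diameter in sorted(strains.items()):
        for _ in range(n_replicates):
            rows.append(
                {
                    "strain": strain,
                    "diameter_cm": max(0.0, diameter + rng.normal(0.0, noise_sd_cm)),
                }
            )
    return pd.DataFrame(rows)
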