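"""Mutation-call filtering, coding-effect annotation and parallelism tables.

Mirrors the downstream handling of breseq-style calls in a multi-lineage
evolution experiment: calls with marginal read support are dropped, alleles
shared by most lineages are treated as ancestral (acquired during strain
construction, not during evolution), surviving records are annotated against
a GFF3 annotation, and the annotated targets are tabulated across lineages
to expose parallel evolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats as scipy_stats

from .io import Feature, GenomeAnnotation, MutationRecord

logger = logging.getLogger(__name__)

#: Feature types treated as genes when assigning mutation targets.
GENE_TYPES = ("gene", "CDS")
#: Feature types treated as mobile-element (IS) annotations.
IS_TYPES = ("mobile_genetic_element", "repeat_region", "mobile_element")


def filter_marginal_calls(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Drop calls whose mutant read fraction is <= 0.5.

    A call supported by an equal or greater mix of reference reads is
    considered marginal. Records without read-support information pass
    through unfiltered.
    """
    kept = []
    for rec in records:
        frac = rec.mutant_read_fraction
        if frac is not None and frac <= 0.5:
            logger.info("marginal call dropped: %s %s:%s", rec.type, rec.seqid, rec.position)
            continue
        kept.append(rec)
    return kept


def filter_ancestral(
    records: Sequence[MutationRecord], min_shared_lineages: int = 6
) -> list[MutationRecord]:
    """Remove alleles present in at least ``min_shared_lineages`` lineages.

    Identical type + coordinate + allele across most lineages indicates a
    mutation acquired in the construction of the common ancestor rather than
    during evolution. The same *gene* hit by different alleles is genuine
    parallelism and is retained.
    """
    lineages_by_allele: dict[tuple, set[str]] = {}
    for rec in records:
        if rec.is_mutation and rec.lineage is not None:
            lineages_by_allele.setdefault(rec.allele_key(), set()).add(rec.lineage)
    ancestral = {
        key for key, lins in lineages_by_allele.items() if len(lins) >= min_shared_lineages
    }
    kept = []
    for rec in records:
        if rec.is_mutation and rec.allele_key() in ancestral:
            logger.info(
                "ancestral allele dropped (%d lineages): %s %s:%s",
                len(lineages_by_allele[rec.allele_key()]),
                rec.type,
                rec.seqid,
                rec.position,
            )
            continue
        kept.append(rec)
    return kept


def _containing_gene(annotation: GenomeAnnotation, rec: MutationRecord) -> Feature | None:
    hits = [
        f
        for f in annotation.overlapping(rec.seqid, rec.position, rec.end)
        if f.type in GENE_TYPES
    ]
    # prefer CDS over gene when both annotate the same locus
    hits.sort(key=lambda f: (f.type != "CDS", f.start))
    return hits[0] if hits else None


def _upstream_gene(
    annotation: GenomeAnnotation, rec: MutationRecord, window: int
) -> Feature | None:
    best: tuple[int, Feature] | None = None
    for f in annotation.features:
        if f.type not in GENE_TYPES or f.seqid != rec.seqid:
            continue
        if f.strand == "-":
            distance = rec.position - (f.end - 1)
        else:
            distance = f.start - rec.position
        if 0 < distance <= window and (best is None or distance < best[0]):
            best = (distance, f)
    return best[1] if best else None


def _snp_effect(rec: MutationRecord, cds: Feature, annotation: GenomeAnnotation) -> str | None:
    if annotation.sequences is None or rec.seqid not in annotation.sequences:
        return None
    seq = annotation.sequences[rec.seqid]
    ref_cds = seq[cds.start : cds.end]
    offset = rec.position - cds.start
    mutated = ref_cds[:offset] + rec.new_seq + ref_cds[offset + 1 :]
    if cds.strand == "-":
        ref_cds = str(Seq(ref_cds).reverse_complement())
        mutated = str(Seq(mutated).reverse_complement())
    ref_aa = str(Seq(ref_cds).translate())
    mut_aa = str(Seq(mutated).translate())
    if ref_aa == mut_aa:
        return "synonymous"
    diffs = [i for i, (a, b) in enumerate(zip(ref_aa, mut_aa)) if a != b]
    if any(mut_aa[i] == "*" for i in diffs):
        return "nonsense"
    return "missense"


def annotate_coding_effect(
    record: MutationRecord,
    annotation: GenomeAnnotation,
    upstream_window: int = 2500,
    region_targets: Mapping[str, str] | None = None,
) -> MutationRecord:
    """Return a copy of ``record`` with target, relation and coding effect set.

    Coding SNPs are classified synonymous / missense / nonsense by translating
    the reference and mutated CDS (standard genetic code; start-codon special
    cases are not modelled). In-frame duplications of length L report an
    ``in-frame-dup(+L/3 aa)`` protein extension; any length not divisible by
    three is a frameshift, as are IS insertions into a CDS. Intergenic records
    are assigned to the nearest downstream gene within ``upstream_window`` bp
    (relation ``intergenic-upstream``) or left as ``intergenic-other``.

    ``region_targets`` maps a sequence region id to a single collective
    target name (e.g. an engineered plasmid counted as one target).
    """
    if not record.is_mutation:
        return record
    if not annotation.contains_position(record.seqid, record.position):
        raise ValueError(
            f"record at {record.seqid}:{record.position} outside annotated regions"
        )
    gene = _containing_gene(annotation, record)
    effect: str | None = "none"
    if gene is not None:
        relation = "coding"
        target = gene.locus_tag or gene.feature_id
        if record.type == "SNP":
            effect = _snp_effect(record, gene, annotation)
        elif record.type == "AMP":
            n_extra = record.size * (record.new_copy_number - 1)
            if n_extra % 3 == 0:
                effect = f"in-frame-dup(+{n_extra // 3} aa)"
            else:
                effect = "frameshift"
        elif record.type in ("INS", "DEL", "SUB", "MOB"):
            if record.type == "INS":
                delta = len(record.new_seq)
            elif record.type == "DEL":
                delta = -record.size
            elif record.type == "SUB":
                delta = len(record.new_seq) - record.size
            else:  # MOB: an IS insertion disrupts the reading frame
                delta = 1
            effect = "none" if delta % 3 == 0 else "frameshift"
    else:
        upstream = _upstream_gene(annotation, record, upstream_window)
        if upstream is not None:
            relation = "intergenic-upstream"
            target = upstream.locus_tag or upstream.feature_id
        else:
            relation = "intergenic-other"
            target = None
        effect = "none"
    if region_targets and record.seqid in region_targets:
        target = region_targets[record.seqid]
    return replace(record, target=target, relation=relation, coding_effect=effect)


def annotate_records(
    records: Iterable[MutationRecord],
    annotation: GenomeAnnotation,
    upstream_window: int = 2500,
    region_targets: Mapping[str, str] | None = None,
) -> list[MutationRecord]:
    return [
        annotate_coding_effect(rec, annotation, upstream_window, region_targets)
        if rec.is_mutation
        else rec
        for rec in records
    ]


@dataclass(frozen=True)
class ISMediatedDeletion:
    """A deletion whose endpoints coincide with two homologous IS copies."""

    lineage: str | None
    seqid: str
    start: int
    end: int
    size: int
    is_family: str
    removed_genes: tuple[str, ...]


def detect_is_mediated_deletion(
    records: Sequence[MutationRecord],
    annotation: GenomeAnnotation,
    endpoint_tolerance: int = 100,
) -> list[ISMediatedDeletion]:
    """Find DEL records bounded by two same-family, same-orientation IS copies.

    Recombination between homologous insertion sequences excises the
    intervening segment; such deletions are recognised when each deletion
    endpoint falls within ``endpoint_tolerance`` bp of an annotated IS copy
    and the two copies share family and orientation. The removed-gene list
    contains locus tags of genes fully inside the deleted interval.
    """
    is_features = [f for f in annotation.features if f.type in IS_TYPES]
    out: list[ISMediatedDeletion] = []
    for rec in records:
        if rec.type != "DEL":
            continue
        start, end = rec.position, rec.end

        def _near(point: int) -> list[Feature]:
            return [
                f
                for f in is_features
                if f.seqid == rec.seqid
                and f.start - endpoint_tolerance <= point <= f.end + endpoint_tolerance
            ]

        left, right = _near(start), _near(end)
        pair = None
        for a in left:
            for b in right:
                if a is not b and a.strand == b.strand:
                    fam_a = a.attributes.get("family", a.locus_tag or a.feature_id)
                    fam_b = b.attributes.get("family", b.locus_tag or b.feature_id)
                    if fam_a == fam_b:
                        pair = (a, b, fam_a)
                        break
            if pair:
                break
        if pair is None:
            continue
        removed = tuple(
            f.locus_tag or f.feature_id
            for f in annotation.features
            if f.type in GENE_TYPES
            and f.seqid == rec.seqid
            and f.start >= start
            and f.end <= end
        )
        out.append(
            ISMediatedDeletion(
                lineage=rec.lineage,
                seqid=rec.seqid,
                start=start,
                end=end,
                size=rec.size,
                is_family=pair[2],
                removed_genes=removed,
            )
        )
    return out


def build_target_matrix(
    records: Sequence[MutationRecord],
    target_aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Boolean targets x lineages presence matrix from annotated records.

    ``target_aliases`` merges related loci into one named target (e.g. two
    ATP-synthase subunits counted as one functional target). Records without
    an assigned target are skipped. Both coding and upstream-intergenic hits
    count toward a target.
    """
    pairs: set[tuple[str, str]] = set()
    for rec in records:
        if not rec.is_mutation or rec.target is None or rec.lineage is None:
            continue
        target = (target_aliases or {}).get(rec.target, rec.target)
        pairs.add((target, rec.lineage))
    if not pairs:
        return pd.DataFrame(dtype=bool)
    targets = sorted({t for t, _ in pairs})
    lineages = sorted({l for _, l in pairs})
    matrix = pd.DataFrame(False, index=targets, columns=lineages)
    for target, lineage in pairs:
        matrix.loc[target, lineage] = True
    return matrix


def parallelism_counts(matrix: pd.DataFrame) -> pd.Series:
    """Lineages hit per target (row sums), most parallel first."""
    counts = matrix.sum(axis=1).astype(int)
    return counts.sort_values(ascending=False, kind="stable")


def lineage_summary(records: Sequence[MutationRecord]) -> pd.DataFrame:
    """Per-lineage mutation totals in the style of a strain-summary table.

    Columns: total, intergenic, coding, is_elements (MOB records).
    """
    rows: dict[str, dict[str, int]] = {}
    for rec in records:
        if not rec.is_mutation or rec.lineage is None:
            continue
        row = rows.setdefault(
            rec.lineage, {"total": 0, "intergenic": 0, "coding": 0, "is_elements": 0}
        )
        row["total"] += 1
        if rec.relation == "coding":
            row["coding"] += 1
        elif rec.relation is not None and rec.relation.startswith("intergenic"):
            row["intergenic"] += 1
        if rec.type == "MOB":
            row["is_elements"] += 1
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "lineage"
    return out


def count_covariate_correlation(
    counts: pd.Series, covariate: pd.Series
) -> tuple[float, float]:
    """Spearman rank correlation between per-lineage mutation counts and a
    covariate (e.g. growth improvement or novel-expression gene counts)."""
    common = counts.index.intersection(covariate.index)
    if len(common) < 3:
        raise ValueError("need at least 3 lineages for a rank correlation")
    rho, p = scipy_stats.spearmanr(counts.loc[common], covariate.loc[common])
    return float(rho), float(p)


def records_with_targets(records: Sequence[MutationRecord]) -> pd.DataFrame:
    """Tabular summary of annotated mutation records."""
    rows = [
        {
            "lineage": rec.lineage,
            "type": rec.type,
            "seqid": rec.seqid,
            "position": rec.position,
            "target": rec.target,
            "relation": rec.relation,
            "coding_effect": rec.coding_effect,
            "mutant_read_fraction": rec.mutant_read_fraction,
        }
        for rec in records
        if rec.is_mutation
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "lineage",
            "type",
            "seqid",
            "position",
            "target",
            "relation",
            "coding_effect",
            "mutant_read_fraction",
        ],
    )


def protein_extension_aa(record: MutationRecord) -> int | None:
    """Amino acids added by an in-frame duplication record, if any."""
    if record.coding_effect and record.coding_effect.startswith("in-frame-dup"):
        inner = record.coding_effect.split("+", 1)[1]
        return int(inner.split(" ")[0])
    return None


def type_counts(records: Sequence[MutationRecord]) -> pd.Series:
    frame = records_with_targets(records)
    if frame.empty:
        return pd.Series(dtype=int)
    return frame["type"].value_counts()


def covariate_series(frame: pd.DataFrame, column: str) -> pd.Series:
    if column not in frame.columns:
        raise KeyError(column)
    return pd.Series(np.asarray(frame[column], dtype=float), index=frame.index)
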