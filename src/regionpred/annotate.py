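"""SNP assignment to nested genomic region classes.

Five classes are formed from a gene annotation: CDS (protein-coding
sequence), Exons (CDS + UTR), Genes (CDS + UTR + introns), Genes1kb (genes
plus 1 kb upstream/downstream regulatory flanks) and IGR (intergenic, the
complement). By construction CDS <= Exons <= Genes <= Genes1kb and
IGR = all SNPs minus Genes1kb. A SNP sitting exactly at the flank boundary
(1,000 bp from a gene end) is counted as genic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import SimulatedGenome

__all__ = ["RegionPartition", "MatchedIGRSample", "build_partition",
           "sample_matched_igr", "read_gff3_features"]

GENIC_CLASSES = ("CDS", "Exons", "Genes", "Genes1kb")
ALL_CLASSES = GENIC_CLASSES + ("IGR",)


@dataclass
class RegionPartition:
    """SNP-id sets per region class plus provenance."""

    regions: dict[str, frozenset]
    annotation_source: str = ""
    flank_bp: int = 1000

    def __getitem__(self, name: str) -> frozenset:
        return self.regions[name]

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def validate(self, all_snp_ids) -> None:
        """Assert nesting, complement and union-totality."""
        r = self.regions
        assert r["CDS"] <= r["Exons"] <= r["Genes"] <= r["Genes1kb"]
        universe = frozenset(all_snp_ids)
        assert r["IGR"] == universe - r["Genes1kb"]
        assert r["IGR"] | r["Genes1kb"] == universe
        assert not (r["IGR"] & r["Genes1kb"])

    def write(self, out_dir) -> None:
        """Each class as a one-column SNP-id list; membership is id-based so
        no coordinate conversion is involved."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        for name, ids in self.regions.items():
            with open(os.path.join(out_dir, f"{name}.txt"), "w") as fh:
                for s in sorted(ids):
                    fh.write(s + "\n")

    def write_bed(self, out_dir, snp_map) -> None:
        """Per-class BED files of SNP positions (0-based half-open)."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        coord = {sid: (c, p) for sid, c, p in snp_map}
        for name, ids in self.regions.items():
            rows = sorted((coord[s][0], coord[s][1], s) for s in ids)
            with open(os.path.join(out_dir, f"{name}.bed"), "w") as fh:
                for c, p, s in rows:
                    fh.write(f"{c}\t{p - 1}\t{p}\t{s}\n")


@dataclass(frozen=True)
class MatchedIGRSample:
    """Random intergenic SNP subset matched in size to a genic class."""

    source_region: str
    snp_ids: frozenset
    seed: int


def _merged_intervals(features: list[tuple[str, int, int]]) -> dict[str, np.ndarray]:
    """Union of 1-based closed intervals per chromosome, as sorted arrays."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in features:
        if start > end:
            raise ValueError(f"malformed interval {chrom}:{start}-{end} (start > end)")
        by_chrom.setdefault(chrom, []).append((start, end))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1] + 1:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out, dtype=np.int64)
    return merged


def _members(snp_map, merged: dict[str, np.ndarray]) -> frozenset:
    """SNP ids whose position falls in any merged interval (binary search)."""
    hits = []
    for sid, chrom, pos in snp_map:
        ivs = merged.get(chrom)
        if ivs is None or len(ivs) == 0:
            continue
        k = int(np.searchsorted(ivs[:, 0], pos, side="right")) - 1
        if k >= 0 and pos <= ivs[k, 1]:
            hits.append(sid)
    return frozenset(hits)


def read_gff3_features(gff_path):
    """Extract (chrom, start, end) per feature type (gene/exon/CDS) from GFF3."""
    import gffutils

    db = gffutils.create_db(str(gff_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    feats: dict[str, list[tuple[str, int, int]]] = {"gene": [], "exon": [], "CDS": []}
    for ftype in feats:
        for f in db.features_of_type(ftype):
            feats[ftype].append((f.seqid, f.start, f.end))
    return feats


def build_partition(
    snp_map,
    annotation,
    flank_bp: int = 1000,
) -> RegionPartition:
    """Assign every SNP to the five nested region classes.

    ``annotation`` is a SimulatedGenome, a GFF3 path, or a dict of feature
    lists {"gene"/"exon"/"CDS": [(chrom, start, end), ...]} with 1-based
    closed intervals. The nesting invariant is enforced by unioning each
    class with the classes it contains, so e.g. a CDS SNP is a member of all
    four genic sets even if exon rows were omitted for it.
    """
    if isinstance(annotation, SimulatedGenome):
        feats = {"gene": [], "exon": [], "CDS": []}
        for g in annotation.genes:
            feats["gene"].append((g.chrom, g.start, g.end))
            feats["exon"].extend((g.chrom, s, e) for s, e in g.exons)
            feats["CDS"].extend((g.chrom, s, e) for s, e in g.cds)
        source = "simulated"
    elif isinstance(annotation, dict):
        feats = {"gene": list(annotation.get("gene", ())),
                 "exon": list(annotation.get("exon", ())),
                 "CDS": list(annotation.get("CDS", ()))}
        source = "feature-dict"
    else:
        feats = read_gff3_features(annotation)
        source = str(annotation)

    gene_iv = _merged_intervals(feats["gene"]) if feats["gene"] else {}
    exon_iv = _merged_intervals(feats["exon"]) if feats["exon"] else {}
    cds_iv = _merged_intervals(feats["CDS"]) if feats["CDS"] else {}
    flank_feats = [(c, max(1, int(s) - flank_bp), int(e) + flank_bp)
                   for c, s, e in feats["gene"]]
    flank_iv = _merged_intervals(flank_feats) if flank_feats else {}

    annotated_chroms = set(gene_iv) | set(exon_iv) | set(cds_iv)
    orphan = {c for _, c, _ in snp_map} - annotated_chroms
    if orphan and annotated_chroms:
        warnings.warn(
            f"SNPs on unannotated chromosome(s) {sorted(orphan)} assigned to IGR",
            stacklevel=2,
        )

    cds = _members(snp_map, cds_iv)
    exons = _members(snp_map, exon_iv) | cds
    genes = _members(snp_map, gene_iv) | exons
    genes1kb = _members(snp_map, flank_iv) | genes
    igr = frozenset(s for s, _, _ in snp_map) - genes1kb
    return RegionPartition(
        {"CDS": cds, "Exons": exons, "Genes": genes, "Genes1kb": genes1kb, "IGR": igr},
        annotation_source=source,
        flank_bp=flank_bp,
    )


def sample_matched_igr(
    partition: RegionPartition,
    region_name: str,
    seed: int = 0,
) -> MatchedIGRSample:
    """Uniform sample without replacement from IGR, sized like ``region_name``."""
    region = partition[region_name]
    igr = sorted(partition["IGR"])
    if len(igr) < len(region):
        raise ValueError(
            f"IGR has {len(igr)} SNPs, fewer than |{region_name}| = {len(region)}")
    rng = np.random.default_rng(seed)
    picked = rng.choice(igr, size=len(region), replace=False)
    return MatchedIGRSample(region_name, frozenset(picked.tolist()), seed)
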