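"""End-to-end survey orchestration: identify -> properties -> classify ->
duplicates -> phylogeny -> promoters -> expression -> report.

Stages run in dependency order on a common input bundle; each stage
contributes a table to the RunReport (or an explicit skipped marker).
Reports carry a provenance block (config hash, seed) and are
deterministic for fixed inputs and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import (
    classifiers,
    expression as expr_mod,
    family_catalog as fc,
    fixtures,
    genome_io,
    promoter,
    protein_props,
)
from .duplication import (
    DuplicatePair,
    classify_duplication,
    codon_align,
    divergence_time,
    ng86,
    pairwise_identity,
    selection_class,
)

logger = logging.getLogger(__name__)

__all__ = ["RunReport", "run_pipeline", "table_fixture_mode"]

STAGES = (
    "identify", "props", "classify", "dupes", "promoters", "expr",
)


@dataclass
class RunReport:
    tables: dict[str, pd.DataFrame | dict] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "skipped": self.skipped,
            "warnings": self.warnings,
            "tables": {
                k: (v.to_dict(orient="records")
                    if isinstance(v, pd.DataFrame) else v)
                for k, v in self.tables.items()
            },
        }
        return json.dumps(payload, indent=2, default=str)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            if isinstance(table, pd.DataFrame):
                table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        clustered = self.tables.get("expression_clustered")
        if clustered is not None and len(clustered) >= 2:
            from .expression import plot_heatmap

            plot_heatmap(
                clustered.set_index(clustered.columns[0]),
                outdir / "expression_heatmap.png",
            )
        (outdir / "report.json").write_text(self.to_json())


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _read_fasta_map(path) -> dict[str, str]:
    """Plain id -> sequence map without DNA-alphabet validation (works
    for protein as well as CDS FASTA)."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise genome_io.GenomeIOError(f"duplicate sequence ID {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise genome_io.GenomeIOError(f"{path}: empty or not FASTA")
    return out


def run_pipeline(
    genome_fasta=None,
    gff3=None,
    protein_fasta=None,
    cds_fasta=None,
    domain_hits_tsv=None,
    tissue_matrix_tsv=None,
    tissue_classes_tsv=None,
    stress_matrix_tsv=None,
    stages: tuple[str, ...] = STAGES,
    prefix: str = "Syn",
    seed: int = 0,
    tau: float = expr_mod.DEFAULT_TAU,
) -> RunReport:
    """Run the requested stages; missing required input for a requested
    stage raises a StageError naming the stage and input."""
    report = RunReport()
    report.provenance = {
        "seed": seed,
        "stages": list(stages),
        "config_hash": hashlib.sha256(
            json.dumps(
                [str(p) for p in (genome_fasta, gff3, protein_fasta,
                                  cds_fasta, domain_hits_tsv)],
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16],
    }
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    catalog: fc.FamilyCatalog | None = None
    genes: list[genome_io.GeneModel] = []
    proteins: dict[str, str] = {}
    cds_map: dict[str, str] = {}

    def require(stage: str, value, name: str):
        if value is None:
            raise StageError(stage, f"missing required input {name!r}")
        return value

    for stage in STAGES:
        if stage not in stages:
            report.skipped.append(stage)
            continue
        logger.info("stage %s: start", stage)

        if stage == "identify":
            try:
                genes = genome_io.read_gff3(require("identify", gff3, "gff3"))
                proteins = _read_fasta_map(
                    require("identify", protein_fasta, "protein_fasta")
                )
                hits = fc.read_domain_hits(
                    require("identify", domain_hits_tsv, "domain_hits_tsv")
                )
            except genome_io.GenomeIOError as exc:
                raise StageError("identify", f"genome_io: {exc}") from exc
            tx_to_gene = {
                tx.transcript_id: g
                for g in genes
                for tx in g.transcripts
            }
            members = []
            for pid in proteins:
                family = fc.assign_family(pid, hits)
                if family == "none":
                    continue
                gene = tx_to_gene.get(pid)
                if gene is None:
                    raise StageError("identify", f"protein {pid} not in GFF3")
                members.append(
                    fc.FamilyMember(
                        name=pid,
                        gene_id=gene.gene_id,
                        transcript_id=pid,
                        family=family,
                        protein=proteins[pid],
                        domains=[h for h in hits if h.protein_id == pid],
                        cds_length=3 * (len(proteins[pid]) + 1),
                        pp_length=len(proteins[pid]),
                    )
                )
            catalog = fc.FamilyCatalog(members=members, prefix=prefix)
            coords = {g.gene_id: (g.chrom_id, g.start) for g in genes}
            fc.assign_nomenclature(catalog, coords)
            report.tables["catalog"] = pd.DataFrame(
                [
                    {
                        "name": m.name,
                        "gene_id": m.gene_id,
                        "transcript_id": m.transcript_id,
                        "family": m.family,
                        "pp_length": m.pp_length,
                    }
                    for m in catalog.members
                ]
            )

        elif stage == "props":
            require("props", catalog, "catalog (run identify)")
            for m in catalog.members:
                m.mw = round(protein_props.molecular_weight(m.protein), 1)
                m.pi = round(protein_props.isoelectric_point(m.protein), 2)
            report.tables["props"] = pd.DataFrame(
                [
                    {"name": m.name, "mw_kda": m.mw, "pi": m.pi}
                    for m in catalog.members
                ]
            )

        elif stage == "classify":
            require("classify", catalog, "catalog (run identify)")
            rows = []
            for m in catalog.members:
                if m.family == "GLYI":
                    arch = classifiers.domain_architecture(m)
                    hit = next(
                        h for h in m.domains
                        if h.domain_accession == fc.GLYI_DOMAIN
                    )
                    domain_seq = m.protein[hit.start - 1 : hit.end]
                    from .synthetic_data import (
                        GLYI_SITE_COLUMNS,
                        GLYI_SITE_REFERENCE,
                    )

                    flags = classifiers.detect_glyI_sites(
                        domain_seq,
                        classifiers.SiteReference(
                            GLYI_SITE_REFERENCE, GLYI_SITE_COLUMNS
                        ),
                    )
                    cls = classifiers.classify_glyI(
                        classifiers.GlyIDomainRecord(
                            m.name, len(domain_seq), flags
                        )
                    )
                    rows.append(
                        {
                            "name": m.name, "family": "GLYI",
                            "architecture": arch,
                            "activity": cls.activity, "metal": cls.metal,
                        }
                    )
                else:
                    arch = classifiers.domain_architecture(m)
                    rec = classifiers.classify_glyII(m.protein, m.name)
                    rows.append(
                        {
                            "name": m.name, "family": "GLYII",
                            "architecture": arch,
                            "activity": rec.activity, "metal": "",
                        }
                    )
            report.tables["classifications"] = pd.DataFrame(rows)

        elif stage == "dupes":
            cds_map = _read_fasta_map(require("dupes", cds_fasta, "cds_fasta"))
            require("dupes", catalog, "catalog (run identify)")
            first_iso = {}
            for m in catalog.members:
                first_iso.setdefault(m.gene_id, m)
            gene_list = sorted(
                (g for g in genes if g.gene_id in first_iso),
                key=lambda g: (g.chrom_id, g.start),
            )
            all_genes_sorted = sorted(
                genes, key=lambda g: (g.chrom_id, g.start)
            )
            order_on_chrom = {
                g.gene_id: i
                for i, g in enumerate(all_genes_sorted)
            }
            rows = []
            for i in range(len(gene_list)):
                for j in range(i + 1, len(gene_list)):
                    ga, gb = gene_list[i], gene_list[j]
                    ma, mb = first_iso[ga.gene_id], first_iso[gb.gene_id]
                    ident = pairwise_identity(ma.protein, mb.protein)
                    same_chrom = ga.chrom_id == gb.chrom_id
                    if same_chrom:
                        lo, hi = sorted([ga, gb], key=lambda g: g.start)
                        gap = max(0, hi.start - lo.end)
                        intervening = max(
                            0,
                            order_on_chrom[hi.gene_id]
                            - order_on_chrom[lo.gene_id]
                            - 1,
                        )
                    else:
                        gap, intervening = 10**9, 10**9
                    dup_type = classify_duplication(
                        same_chrom, ident, intervening, gap
                    )
                    if dup_type == "none":
                        continue
                    aln = codon_align(
                        cds_map[ma.transcript_id], cds_map[mb.transcript_id]
                    )
                    _, ka, ks = ng86(aln)
                    rows.append(
                        DuplicatePair(
                            ga.gene_id, gb.gene_id, round(ident, 2),
                            dup_type, ka=round(ka, 4), ks=round(ks, 4),
                            ratio=round(ka / ks, 4) if ks else float("nan"),
                            time_mya=round(divergence_time(ks), 4),
                        )
                    )
            report.tables["duplicate_pairs"] = pd.DataFrame(
                [
                    {
                        "gene_a": p.gene_a, "gene_b": p.gene_b,
                        "identity_pct": p.identity_pct, "type": p.dup_type,
                        "ka": p.ka, "ks": p.ks, "ka_ks": p.ratio,
                        "time_mya": p.time_mya,
                        "selection": selection_class(p.ka, p.ks),
                    }
                    for p in rows
                ]
            )

        elif stage == "promoters":
            genome = genome_io.read_fasta(
                require("promoters", genome_fasta, "genome_fasta")
            )
            genome_by_id = {g.chrom_id: g for g in genome}
            require("promoters", genes, "gene models (run identify)")
            cat = promoter.default_catalog()
            matches = []
            for g in genes:
                seq, _ = genome_io.extract_upstream(
                    genome_by_id[g.chrom_id], g, 1000
                )
                matches.extend(promoter.scan_promoter(seq, cat, g.gene_id))
            report.tables["cis_matches"] = pd.DataFrame(
                [
                    {
                        "gene": m.gene_id, "element": m.element,
                        "strand": m.strand, "position": m.position,
                        "sequence": m.matched_seq,
                    }
                    for m in matches
                ]
            )
            census = promoter.element_census(matches)
            report.tables["cis_census"] = census.reset_index()

        elif stage == "expr":
            tissue = pd.read_csv(
                require("expr", tissue_matrix_tsv, "tissue_matrix_tsv"),
                sep="\t", index_col=0,
            )
            classes = pd.read_csv(
                require("expr", tissue_classes_tsv, "tissue_classes_tsv"),
                sep="\t", index_col=0,
            ).iloc[:, 0].to_dict()
            calls = {
                g: expr_mod.specificity_class(tissue.loc[g], classes, tau)
                for g in tissue.index
            }
            rows = [{"gene": g, "specificity": c} for g, c in calls.items()]
            if stress_matrix_tsv is not None:
                stress = pd.read_csv(
                    stress_matrix_tsv, sep="\t", index_col=0
                )
                for row in rows:
                    g = row["gene"]
                    if g in stress.index:
                        f = expr_mod.fold_change(
                            stress.loc[g, "stress"], stress.loc[g, "mock"]
                        )
                        row["fold_change"] = round(f, 4)
                        row["regulation"] = expr_mod.regulation_call(f)
            report.tables["expression_calls"] = pd.DataFrame(rows)
            if tissue.shape[0] >= 2:
                link, ordered = expr_mod.hierarchical_cluster(tissue)
                report.tables["expression_clustered"] = ordered.reset_index()

        logger.info("stage %s: done", stage)
    return report


def table_fixture_mode() -> RunReport:
    """Recompute all derivable columns from the packaged printed tables
    and report agreement counts."""
    report = RunReport()
    report.provenance = {"mode": "fixtures"}
    report.tables["pairs"] = fixtures.recompute_pair_table()
    report.tables["glyi_classifications"] = (
        fixtures.recompute_glyi_classifications()
    )
    report.tables["glyii_classifications"] = (
        fixtures.recompute_glyii_classifications()
    )
    report.tables["summary"] = fixtures.fixture_report()
    return report
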