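"""End-to-end orchestration: load/label -> align -> tree -> logos ->
two-sample enrichment -> signature extraction -> role classification.

Every stage is a pure function of (inputs, config, seed); the run writes
each artifact with a sha256 checksum into a manifest and a ``summary.json``
that is byte-identical across re-runs with the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import align as al
from . import conservation as cons
from . import phylo, signature, two_sample
from .errors import OrthoSignatureError, ValidationError
from .seqio import (GAP, MasterAlignment, ProteinSequence, SpeciesRecord,
                    load_table1, read_fasta, read_species_table, write_fasta,
                    write_newick)

log = logging.getLogger("ortho_signature.pipeline")


@dataclass
class RunConfig:
    gene_fastas: dict[str, str]            # gene name -> FASTA path
    out_dir: str
    species_table: str | None = None       # None -> shipped study table
    prealigned: bool = False
    groups: dict[str, list[str]] | None = None  # explicit role -> seq ids
    bootstrap_reps: int = 100
    collapse_threshold: float = 70.0
    alpha: float = 0.05
    correction: str = "bonferroni"
    theta_cons: float = 0.9
    theta_disc: float = 0.2
    min_len: int = 6
    min_fA: float = 0.7
    max_fB: float = 0.3
    scheme_json: str | None = None         # override classifier scheme
    anchor_id: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for th in (self.theta_cons, self.theta_disc, self.min_fA, self.max_fB):
            if not 0.0 <= th <= 1.0:
                raise ValidationError("thresholds must lie in [0, 1]")
        for gene, path in self.gene_fastas.items():
            if not Path(path).exists():
                raise ValidationError(f"input FASTA for {gene!r} not found: {path}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _role_groups(aln: MasterAlignment, records: list[SpeciesRecord], gene: str,
                 explicit: dict[str, list[str]] | None) -> dict[str, list[str]]:
    """role -> row ids, from explicit lists or accession matching."""
    if explicit is not None:
        groups = {role: [i for i in ids if i in aln.ids]
                  for role, ids in explicit.items()}
    else:
        by_acc = {rec.accessions.get(gene): rec for rec in records}
        groups = {}
        for rid in aln.ids:
            rec = by_acc.get(rid)
            role = rec.role_label if rec is not None else "unknown"
            groups.setdefault(role, []).append(rid)
    return groups


def _order_grouping(aln: MasterAlignment, records: list[SpeciesRecord],
                    gene: str, explicit: dict[str, list[str]] | None) -> dict[str, str]:
    if explicit is not None:
        return {i: role for role, ids in explicit.items() for i in ids if i in aln.ids}
    by_acc = {rec.accessions.get(gene): rec for rec in records}
    return {rid: (by_acc[rid].order if rid in by_acc else "unassigned")
            for rid in aln.ids}


def _derive_scheme(table: two_sample.EnrichmentTable, diag: list[tuple[int, str, str]],
                   anchor_id: str) -> signature.SignatureScheme | None:
    positions, gsets, lsets = [], [], []
    for pos, res_a, res_b in diag:
        if res_b == GAP or res_a == res_b:
            continue
        positions.append(pos)
        gsets.append({res_a})
        lsets.append({res_b})
    if len(positions) < 2:
        return None
    return signature.SignatureScheme(name="derived", anchor_id=anchor_id,
                                     positions=positions, global_consensus=gsets,
                                     local_consensus=lsets, coordinate="master")


def run_gene(gene: str, fasta: str, records: list[SpeciesRecord],
             config: RunConfig, out: Path) -> tuple[dict, dict[str, str]]:
    """All stages for one gene family; returns (summary dict, artifact paths)."""
    artifacts: dict[str, str] = {}
    log.info("[%s] load + align (prealigned=%s)", gene, config.prealigned)
    if config.prealigned:
        aln = read_fasta(fasta, gapped=True)
        if not isinstance(aln, MasterAlignment):
            raise OrthoSignatureError("expected alignment FASTA")
    else:
        seqs = read_fasta(fasta)
        aln = al.progressive_msa(seqs)
    aln_path = out / f"{gene}_aln.fasta"
    write_fasta(aln, aln_path)
    artifacts["alignment"] = str(aln_path)

    groups = _role_groups(aln, records, gene, config.groups)
    order_grouping = _order_grouping(aln, records, gene, config.groups)

    log.info("[%s] tree: %d bootstrap reps, collapse < %g%%",
             gene, config.bootstrap_reps, config.collapse_threshold)
    tree = phylo.bootstrap_support(aln, config.bootstrap_reps, config.seed)
    tree_path = out / f"{gene}_tree.nwk"
    write_newick(tree, tree_path)
    artifacts["tree"] = str(tree_path)
    collapsed = phylo.collapse_low_support(tree, config.collapse_threshold)
    coll_path = out / f"{gene}_tree_collapsed.nwk"
    write_newick(collapsed, coll_path)
    artifacts["tree_collapsed"] = str(coll_path)
    coherence = phylo.clade_coherence(tree, order_grouping)
    coherence_collapsed = phylo.clade_coherence(collapsed, order_grouping)

    log.info("[%s] per-group logos", gene)
    logo_paths = {}
    profiles_by_role = {}
    for role, ids in sorted(groups.items()):
        if not ids:
            continue
        profiles = cons.column_profiles(aln, ids)
        profiles_by_role[role] = profiles
        ptab = cons.profiles_to_table(profiles, group_label=role)
        p = out / f"{gene}_logo_{role}.tsv"
        ptab.to_csv(p, sep="\t", index=False)
        logo_paths[role] = str(p)
    artifacts.update({f"logo_{r}": p for r, p in logo_paths.items()})

    summary: dict = {
        "gene": gene,
        "n_sequences": len(aln),
        "alignment_length": aln.length,
        "group_sizes": {r: len(ids) for r, ids in sorted(groups.items())},
        "order_counts": {},
        "clade_coherence": {k: bool(v) for k, v in sorted(coherence.items())},
        "clade_coherence_collapsed": {k: bool(v)
                                      for k, v in sorted(coherence_collapsed.items())},
    }
    for rid, grp in order_grouping.items():
        summary["order_counts"][grp] = summary["order_counts"].get(grp, 0) + 1
    summary["order_counts"] = dict(sorted(summary["order_counts"].items()))

    g_ids = groups.get("global", [])
    l_ids = groups.get("local", [])
    u_ids = groups.get("unknown", [])
    if len(g_ids) >= 2 and len(l_ids) >= 2:
        log.info("[%s] two-sample logo: %d global vs %d local (alpha=%g, %s)",
                 gene, len(g_ids), len(l_ids), config.alpha, config.correction)
        table = two_sample.two_sample_logo(aln, g_ids, l_ids, alpha=config.alpha,
                                           correction=config.correction,
                                           group_A_label="global",
                                           group_B_label="local")
        enr_path = out / f"{gene}_enrichment.tsv"
        table.to_frame().to_csv(enr_path, sep="\t", index=False)
        artifacts["enrichment"] = str(enr_path)
        diag = two_sample.diagnostic_positions(table, config.min_fA, config.max_fB)
        summary["diagnostic_positions"] = [
            {"position": p, "global": ra, "local": rb} for p, ra, rb in diag]

        segments = signature.extract_segments(
            profiles_by_role["global"], profiles_by_role["local"],
            config.theta_cons, config.theta_disc, config.min_len,
            focal_group="global")
        seg_path = out / f"{gene}_segments.json"
        seg_path.write_text(json.dumps(
            [{"start": s.start, "end": s.end, "pattern": s.pattern,
              "focal_group": s.focal_group} for s in segments], indent=2))
        artifacts["segments"] = str(seg_path)
        summary["n_signature_segments"] = len(segments)

        if config.scheme_json:
            scheme = signature.SignatureScheme.from_json(config.scheme_json)
        else:
            anchor = config.anchor_id or (g_ids[0] if g_ids else aln.ids[0])
            scheme = _derive_scheme(table, diag, anchor)
        if scheme is not None and scheme.anchor_id in aln.ids and u_ids:
            log.info("[%s] classifying %d unknown-role sequences on %d-position scheme",
                     gene, len(u_ids), scheme.n_positions)
            preds = []
            for rid in u_ids:
                q = ProteinSequence(id=rid, residues=aln.degapped(rid))
                pred = signature.classify_role(q, scheme, aln)
                preds.append({
                    "query_id": pred.query_id, "call": pred.call,
                    "matches_global": pred.matches_global,
                    "matches_local": pred.matches_local,
                    "n_positions": pred.n_positions,
                    "identity_to_anchor": pred.identity_to_anchor,
                    "low_confidence": pred.low_confidence,
                })
            pred_path = out / f"{gene}_predictions.json"
            pred_path.write_text(json.dumps(preds, indent=2))
            artifacts["predictions"] = str(pred_path)
            summary["role_predictions"] = preds
    return summary, artifacts


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage for every configured gene; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.species_table:
        records = read_species_table(config.species_table)
    else:
        records = load_table1()
    summaries: dict[str, dict] = {}
    manifest_files: dict[str, dict[str, str]] = {}
    for gene, fasta in sorted(config.gene_fastas.items()):
        try:
            summary, artifacts = run_gene(gene, fasta, records, config, out)
        except Exception as exc:
            partial = out / "summary.json.partial"
            partial.write_text(json.dumps(summaries, indent=2, sort_keys=True))
            raise OrthoSignatureError(f"stage failure in gene {gene!r}: {exc}") from exc
        summaries[gene] = summary
        manifest_files[gene] = {k: _sha256(Path(p)) for k, p in artifacts.items()}
    summary_obj = {
        "seed": config.seed,
        "parameters": {
            "bootstrap_reps": config.bootstrap_reps,
            "collapse_threshold": config.collapse_threshold,
            "alpha": config.alpha, "correction": config.correction,
            "theta_cons": config.theta_cons, "theta_disc": config.theta_disc,
            "min_len": config.min_len, "min_fA": config.min_fA,
            "max_fB": config.max_fB,
        },
        "genes": summaries,
        "checksums": manifest_files,
    }
    (out / "summary.json").write_text(json.dumps(summary_obj, indent=2, sort_keys=True))
    return summary_obj
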