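"""Join differential IR, protein, junction-peptide and mRNA results.

Three comparative views:

* stimulus partition — which differential proteins respond only to COLL,
  only to TRAP, or to both (and whether common responses agree in sign);
* protein-mRNA scatter — each differential protein paired with its
  transcript's expression change, to ask whether protein changes are
  transcriptionally driven (in platelets they largely are not: the cells
  are anucleate, so protein accumulation without mRNA change points to
  translation of resident transcripts);
* validation table — the per-gene joint view of intron removal, protein
  accumulation and junction-peptide accumulation.  A gene is ``validated``
  for a stimulus when a significantly removed intron coincides with a
  significant protein or junction-peptide increase; ``partial`` when only
  one side of the evidence is present; ``not_significant`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diff_stats import DiffTestConfig, adjust_p, permutation_test
from .ir_quant import compute_fpkm


@dataclass
class StimulusPartition:
    coll_only: set
    trap_only: set
    common: set
    common_direction: dict  # {"both_down": n, "both_up": n, "discordant": n}

    def validate(self) -> None:
        assert not (self.coll_only & self.trap_only)
        assert not (self.coll_only & self.common)
        assert not (self.trap_only & self.common)


def partition_stimulus_sets(
    coll_results: pd.DataFrame, trap_results: pd.DataFrame
) -> StimulusPartition:
    """Set algebra on significant features of two stimulus comparisons."""
    coll = _sig_effects(coll_results)
    trap = _sig_effects(trap_results)
    common = set(coll) & set(trap)
    direction = {"both_down": 0, "both_up": 0, "discordant": 0}
    for f in common:
        if coll[f] < 0 and trap[f] < 0:
            direction["both_down"] += 1
        elif coll[f] > 0 and trap[f] > 0:
            direction["both_up"] += 1
        else:
            direction["discordant"] += 1
    part = StimulusPartition(
        coll_only=set(coll) - common, trap_only=set(trap) - common,
        common=common, common_direction=direction)
    part.validate()
    return part


def _sig_effects(results: pd.DataFrame) -> dict:
    sig = results[results["significant"].astype(bool)]
    return dict(zip(sig["feature_id"], sig["effect"]))


# ---------------------------------------------------------------------------
# transcript expression
# ---------------------------------------------------------------------------

def transcript_expression(
    counts: pd.DataFrame,
    exon_lengths: pd.Series,
    groups: dict[str, str],
    config: DiffTestConfig,
    treated: str,
    ctrl: str = "CTRL",
    min_reads: int = 10,
) -> pd.DataFrame:
    """Per-gene expression records and a simple differential-expression call.

    ``counts`` is genes x samples of fragment counts.  FPKM normalizes by
    union-exon length and per-sample totals; a gene counts as expressed in a
    group when its mean fragment count there is >= ``min_reads``.  The
    log2FC is the ratio of group mean FPKM, with significance from the
    pooled permutation test on log2(1 + FPKM) and BH adjustment at
    ``fdr_rna`` combined with the ``fc_cutoff_rna`` linear ratio — a
    deliberately simple substitute for a negative-binomial model, adequate
    for the toy scale the generator produces.
    """
    samples = [s for s in counts.columns if groups.get(s) in (treated, ctrl)]
    totals = counts.sum(axis=0)
    fpkm = pd.DataFrame({
        s: compute_fpkm(counts[s], exon_lengths.loc[counts.index], float(totals[s]))
        for s in counts.columns}, index=counts.index)
    tr = [s for s in samples if groups[s] == treated]
    ct = [s for s in samples if groups[s] == ctrl]
    expressed = (counts[ct].mean(axis=1) >= min_reads) | (
        counts[tr].mean(axis=1) >= min_reads)
    mean_tr = fpkm[tr].mean(axis=1)
    mean_ct = fpkm[ct].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_tr.to_numpy()) - np.log2(mean_ct.to_numpy())
    res = permutation_test(np.log2(1.0 + fpkm[samples]), groups, treated, ctrl, config)
    p_adj = adjust_p(res["p_perm"], "bh_fdr")
    significant = (p_adj <= config.fdr_rna) & (
        np.abs(log2fc) >= np.log2(config.fc_cutoff_rna)) & expressed.to_numpy()
    out = pd.DataFrame({
        "gene_id": counts.index,
        "mean_count_ctrl": counts[ct].mean(axis=1).to_numpy(),
        "mean_count_treated": counts[tr].mean(axis=1).to_numpy(),
        "mean_fpkm_ctrl": mean_ct.to_numpy(),
        "mean_fpkm_treated": mean_tr.to_numpy(),
        "expressed": expressed.to_numpy(),
        "log2fc": log2fc,
        "p_adj": p_adj,
        "significant": significant,
    })
    return out


# ---------------------------------------------------------------------------
# protein-mRNA scatter
# ---------------------------------------------------------------------------

def protein_mrna_scatter(
    protein_results: pd.DataFrame,
    expression: pd.DataFrame,
    protein_to_gene: dict[str, str],
    config: DiffTestConfig,
) -> pd.DataFrame:
    """Pair each differential protein with its transcript's change.

    ``mrna_class`` is ``concordant`` (mRNA passes |FC| and FDR thresholds
    with the same sign), ``discordant`` (passes with opposite sign), or
    ``protein_only`` (mRNA change fails the thresholds) — with missing mRNA
    fields when no transcript matches.
    """
    expr = expression.set_index("gene_id")
    rows = []
    for _, r in protein_results[protein_results["significant"].astype(bool)].iterrows():
        gene = protein_to_gene.get(r["feature_id"])
        row = {"protein_id": r["feature_id"], "gene_id": gene,
               "protein_log2fc": r["effect"]}
        if gene is None or gene not in expr.index:
            row.update({"mrna_log2fc": np.nan, "mrna_significant": False,
                        "mrna_class": "no_transcript"})
        else:
            e = expr.loc[gene]
            passes = bool(e["significant"])
            row["mrna_log2fc"] = e["log2fc"]
            row["mrna_significant"] = passes
            if not passes:
                row["mrna_class"] = "protein_only"
            elif np.sign(e["log2fc"]) == np.sign(r["effect"]):
                row["mrna_class"] = "concordant"
            else:
                row["mrna_class"] = "discordant"
        rows.append(row)
    return pd.DataFrame(rows, columns=[
        "protein_id", "gene_id", "protein_log2fc", "mrna_log2fc",
        "mrna_significant", "mrna_class"])


# ---------------------------------------------------------------------------
# validation table
# ---------------------------------------------------------------------------

def classify_validation(ir_sig_down: bool, protein_sig_up: bool,
                        peptide_sig_up: bool) -> str:
    """Deterministic class from the three evidence flags."""
    accumulation = protein_sig_up or peptide_sig_up
    if ir_sig_down and accumulation:
        return "validated"
    if ir_sig_down or accumulation:
        return "partial"
    return "not_significant"


def build_validation_table(
    ir_results: dict[str, pd.DataFrame],
    protein_results: dict[str, pd.DataFrame],
    junction_peptides: dict[str, pd.DataFrame],
    protein_to_gene: dict[str, str],
    junction_to_gene: dict[str, str],
    intron_to_gene: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene, per-stimulus joint view of removal and accumulation.

    All three inputs are keyed by stimulus.  Junction and protein results
    are mapped to genes; intron ids default to the ``gene:tx:idx``
    convention.  Cells that are not significant are left as the neutral
    evidence state (the gray convention of a significance heatmap).
    """
    rows = []
    stimuli = sorted(set(ir_results) | set(protein_results) | set(junction_peptides))
    gene_to_protein = {g: p for p, g in protein_to_gene.items()}
    for stim in stimuli:
        ir = ir_results.get(stim, pd.DataFrame(columns=["feature_id", "effect", "significant"]))
        prot = protein_results.get(stim, pd.DataFrame(columns=["feature_id", "effect", "significant"]))
        pep = junction_peptides.get(stim, pd.DataFrame(
            columns=["junction_id", "log2fc", "significant", "detected"]))
        ir_by_gene: dict[str, tuple[float, bool]] = {}
        for _, r in ir.iterrows():
            gene = (intron_to_gene or {}).get(
                r["feature_id"], str(r["feature_id"]).split(":")[0])
            cur = ir_by_gene.get(gene)
            # keep the strongest removal signal per gene
            if cur is None or (r["significant"] and r["effect"] < cur[0]):
                ir_by_gene[gene] = (r["effect"], bool(r["significant"]))
        prot_by_gene = {
            protein_to_gene.get(r["feature_id"], r["feature_id"]):
                (r["effect"], bool(r["significant"]))
            for _, r in prot.iterrows()}
        pep_by_gene: dict[str, tuple[float, bool]] = {}
        for _, r in pep.iterrows():
            if not r["detected"]:
                continue
            gene = junction_to_gene.get(r["junction_id"])
            if gene is not None:
                pep_by_gene[gene] = (r["log2fc"], bool(r["significant"]))
        genes = sorted(set(ir_by_gene) | set(pep_by_gene)
                       | {g for g in prot_by_gene if g in ir_by_gene or g in pep_by_gene})
        for gene in genes:
            d_ir, ir_sig = ir_by_gene.get(gene, (np.nan, False))
            d_pr, pr_sig = prot_by_gene.get(gene, (np.nan, False))
            d_pe, pe_sig = pep_by_gene.get(gene, (np.nan, False))
            cls = classify_validation(
                ir_sig and d_ir < 0, pr_sig and d_pr > 0, pe_sig and d_pe > 0)
            rows.append({
                "gene_id": gene, "stimulus": stim,
                "protein_id": gene_to_protein.get(gene, ""),
                "delta_ir": d_ir, "ir_significant": ir_sig,
                "protein_log2fc": d_pr, "protein_significant": pr_sig,
                "junction_peptide_log2fc": d_pe, "peptide_significant": pe_sig,
                "class": cls})
    return pd.DataFrame(rows, columns=[
        "gene_id", "stimulus", "protein_id", "delta_ir", "ir_significant",
        "protein_log2fc", "protein_significant", "junction_peptide_log2fc",
        "peptide_significant", "class"])
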