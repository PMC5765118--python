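"""Map identified peptides onto translated junction windows.

A peptide supports intron removal only when its coding span straddles the
exon-exon boundary: with the junction at nucleotide offset ``L`` of the
spliced window and a match occupying amino acids [aa_start, aa_end) of a
frame translation, the coding nucleotides are
[frame + 3*aa_start, frame + 3*aa_end), and the match spans the junction
iff nt_start < L and nt_end > L (at least one coding nucleotide on each
side).  Matches are exact substring occurrences; spans containing a stop
codon are biologically impossible and discarded.  I/L equivalence (the two
residues are isobaric and indistinguishable to the mass spectrometer) is
available behind a flag but off by default, since sequence-level matching
can afford to be stricter than spectral search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diff_stats import DiffTestConfig, adjust_p, permutation_test
from .junction_db import JunctionFrameEntry

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class JunctionPeptideMatch:
    peptide_seq: str
    junction_id: str
    frame: int
    aa_start: int
    aa_end: int
    L: int

    @property
    def nt_start(self) -> int:
        return self.frame + 3 * self.aa_start

    @property
    def nt_end(self) -> int:
        return self.frame + 3 * self.aa_end

    @property
    def spans_junction(self) -> bool:
        return spans_junction(self.nt_start, self.nt_end, self.L)


def spans_junction(nt_start: int, nt_end: int, L: int) -> bool:
    """True iff the coding span has >= 1 nt on each side of the junction."""
    return nt_start < L and nt_end > L


def _validate_peptide(pep: str) -> str:
    if not pep:
        raise ValueError("empty peptide sequence")
    pep = pep.upper()
    bad = set(pep) - AMINO_ACIDS
    if bad:
        raise ValueError(f"peptide {pep!r}: invalid residue(s) {sorted(bad)}")
    return pep


def _il_fold(seq: str) -> str:
    return seq.replace("L", "I")


def match_peptides(
    peptides: list[str],
    entries: list[JunctionFrameEntry],
    il_equivalent: bool = False,
) -> list[JunctionPeptideMatch]:
    """All exact substring occurrences of each peptide in each frame entry.

    With ``il_equivalent`` the comparison treats I and L as interchangeable.
    Occurrences whose amino-acid span contains ``*`` are discarded.
    """
    validated = [_validate_peptide(p) for p in peptides]
    matches: list[JunctionPeptideMatch] = []
    for entry in entries:
        hay = _il_fold(entry.aa_seq) if il_equivalent else entry.aa_seq
        for pep in validated:
            needle = _il_fold(pep) if il_equivalent else pep
            start = hay.find(needle)
            while start != -1:
                end = start + len(needle)
                if "*" not in entry.aa_seq[start:end]:
                    matches.append(JunctionPeptideMatch(
                        peptide_seq=pep, junction_id=entry.junction_id,
                        frame=entry.frame, aa_start=start, aa_end=end, L=entry.L))
                start = hay.find(needle, start + 1)
    return matches


def read_peptide_table(path) -> pd.DataFrame:
    """Peptide TSV: ``peptide_seq`` [, ``protein_id``] + one column per sample."""
    df = pd.read_csv(path, sep="\t")
    if "peptide_seq" not in df.columns:
        raise ValueError("peptide table needs a 'peptide_seq' column")
    return df


def peptide_sample_columns(peptide_df: pd.DataFrame) -> list[str]:
    return [c for c in peptide_df.columns if c not in ("peptide_seq", "protein_id")]


def quantify_junction_peptides(
    matches: list[JunctionPeptideMatch],
    peptide_df: pd.DataFrame,
    groups: dict[str, str],
    config: DiffTestConfig,
    treated: str,
    ctrl: str = "CTRL",
    junction_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-junction change of junction-spanning peptide abundance.

    Spanning-peptide abundances are summed per junction and sample; the
    effect is the log2 ratio of treated vs control median sums, with
    significance from the pooled permutation test on log2(1 + sum) values
    and BH adjustment.  Junctions without any spanning peptide are reported
    with ``detected = False``.
    """
    samples = peptide_sample_columns(peptide_df)
    spanning = [m for m in matches if m.spans_junction]
    by_junction: dict[str, set[str]] = {}
    for m in spanning:
        by_junction.setdefault(m.junction_id, set()).add(m.peptide_seq)
    all_junctions = junction_ids if junction_ids is not None else sorted(by_junction)

    pep_values = peptide_df.set_index("peptide_seq")[samples]
    sums = {}
    for jid, peps in by_junction.items():
        sums[jid] = pep_values.loc[sorted(peps)].sum(axis=0)
    rows = []
    if sums:
        sum_df = pd.DataFrame(sums).T  # junction x sample
        tr = [s for s in samples if groups.get(s) == treated]
        ct = [s for s in samples if groups.get(s) == ctrl]
        log_sums = np.log2(1.0 + sum_df)
        effect = np.log2(sum_df[tr].median(axis=1).clip(lower=1e-12)) - np.log2(
            sum_df[ct].median(axis=1).clip(lower=1e-12))
        res = permutation_test(log_sums, groups, treated, ctrl, config)
        p_adj = adjust_p(res["p_perm"], "bh_fdr")
        for i, jid in enumerate(sum_df.index):
            rows.append({
                "junction_id": jid,
                "n_spanning_peptides": len(by_junction[jid]),
                "log2fc": float(effect.iloc[i]),
                "p_perm": float(res["p_perm"].iloc[i]),
                "p_adj": float(p_adj[i]),
                "significant": bool(p_adj[i] <= config.fdr_ir),
                "detected": True,
            })
    detected_ids = set(by_junction)
    for jid in all_junctions:
        if jid not in detected_ids:
            rows.append({
                "junction_id": jid, "n_spanning_peptides": 0,
                "log2fc": np.nan, "p_perm": np.nan, "p_adj": np.nan,
                "significant": False, "detected": False,
            })
    return pd.DataFrame(rows, columns=[
        "junction_id", "n_spanning_peptides", "log2fc", "p_perm", "p_adj",
        "significant", "detected"])
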