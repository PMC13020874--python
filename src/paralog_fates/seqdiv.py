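"""Codon-level sequence divergence between paralogs.

Implements the Nei–Gojobori (1986) counting estimator of synonymous and
non-synonymous divergence with Jukes–Cantor multiple-hit correction, a
per-gene dN:dS (omega) summary over a set of orthologs, the pre-/post-
duplication pairwise dN table used for asymmetry analysis, and Cliff's
delta, the nonparametric effect size used to compare dN distributions
between paralogs.

The counting estimator is used throughout as a fully specified, testable
alternative to maximum-likelihood codon models: under the purifying
regimes analysed here (omega <= 1) it recovers the same asymmetry
signals, although individual values are not expected to coincide with ML
estimates.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

NUCLEOTIDES = "TCAG"
_NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

#: conventional threshold above which a Cliff's delta magnitude is "large"
CLIFF_LARGE_THRESHOLD = 0.47


def _standard_code() -> dict[str, str]:
    """Codon -> amino acid map for the standard genetic code; stops map to '*'."""
    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


class CodonCode:
    """Precomputed NG86 machinery for one genetic code.

    Holds, for every sense codon, the fractional count of synonymous and
    non-synonymous sites, and for every ordered codon pair the expected
    number of synonymous/non-synonymous differences averaged over all
    minimal substitution paths that avoid stop codons (equal weights; if
    every minimal path passes through a stop codon, all paths are used).
    """

    def __init__(self, code: Mapping[str, str] | None = None):
        self.code = dict(code) if code is not None else _standard_code()
        self.codons = ["".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)]
        self.index = {c: i for i, c in enumerate(self.codons)}
        self.aa = np.array([self.code[c] for c in self.codons])
        self.is_stop = self.aa == "*"
        self.sense_codons = [c for c in self.codons if self.code[c] != "*"]

        syn = np.full(64, np.nan)
        for c in self.codons:
            if self.code[c] == "*":
                continue
            syn[self.index[c]] = self._count_syn_sites(c)
        self.syn_sites = syn
        self.nonsyn_sites = np.where(np.isnan(syn), np.nan, 3.0 - syn)

        self.nd_table, self.sd_table = self._build_difference_tables()

    # -- site counting -------------------------------------------------

    def _count_syn_sites(self, codon: str) -> float:
        aa = self.code[codon]
        syn = 0.0
        for pos in range(3):
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                neighbor = codon[:pos] + nt + codon[pos + 1 :]
                # stop-codon neighbors count as non-synonymous changes
                if self.code[neighbor] == aa:
                    syn += 1.0 / 3.0
        return syn

    # -- pairwise difference counting ----------------------------------

    def _path_changes(self, path: Sequence[str]) -> tuple[float, float]:
        nd = sd = 0.0
        for a, b in zip(path[:-1], path[1:]):
            if self.code[a] == self.code[b]:
                sd += 1
            else:
                nd += 1
        return nd, sd

    def _build_difference_tables(self) -> tuple[np.ndarray, np.ndarray]:
        nd_t = np.zeros((64, 64))
        sd_t = np.zeros((64, 64))
        for ci, c1 in enumerate(self.codons):
            if self.is_stop[ci]:
                continue
            for cj, c2 in enumerate(self.codons):
                if self.is_stop[cj] or cj <= ci:
                    continue
                diff = [p for p in range(3) if c1[p] != c2[p]]
                if not diff:
                    continue
                paths = []
                for order in itertools.permutations(diff):
                    cur = c1
                    path = [c1]
                    for pos in order:
                        cur = cur[:pos] + c2[pos] + cur[pos + 1 :]
                        path.append(cur)
                    paths.append(path)
                stop_free = [
                    p for p in paths if not any(self.code[c] == "*" for c in p[1:-1])
                ]
                usable = stop_free if stop_free else paths
                nd = np.mean([self._path_changes(p)[0] for p in usable])
                sd = np.mean([self._path_changes(p)[1] for p in usable])
                nd_t[ci, cj] = nd_t[cj, ci] = nd
                sd_t[ci, cj] = sd_t[cj, ci] = sd
        return nd_t, sd_t

    def encode(self, seq: str) -> np.ndarray:
        """Encode an in-frame nucleotide sequence as codon indices.

        Codons containing gaps, Ns or other ambiguity characters encode
        as -1 and are skipped pairwise downstream. Stop codons encode
        as -1 as well (they carry no NG86 site counts).
        """
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3 != 0:
            raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
        out = np.full(len(seq) // 3, -1, dtype=np.int64)
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            idx = self.index.get(codon)
            if idx is not None and not self.is_stop[idx]:
                out[i // 3] = idx
        return out


#: module-level singleton for the standard genetic code
STANDARD_CODE = CodonCode()


def count_codon_sites(codon: str, code: CodonCode | None = None) -> tuple[float, float]:
    """Fractional synonymous and non-synonymous site counts of a sense codon.

    For each of the three positions, the fraction of the three
    single-nucleotide neighbors that leave the amino acid unchanged is
    summed; neighbors that are stop codons count as non-synonymous. The
    two counts always sum to 3.
    """
    code = code or STANDARD_CODE
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or any(n not in _NT_INDEX for n in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    idx = code.index[codon]
    if code.is_stop[idx]:
        raise ValueError(f"stop codon not allowed: {codon}")
    return float(code.syn_sites[idx]), float(code.nonsyn_sites[idx])


@dataclass
class DivergenceEstimate:
    """NG86 divergence summary for one sequence pair (or ortholog set).

    ``dN``/``dS`` are Jukes–Cantor-corrected; ``None`` marks an undefined
    quantity (saturation, or omega with dS == 0), with the reason in
    ``flags``.
    """

    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    omega: float | None
    n_codons_compared: int = 0
    flags: list[str] = field(default_factory=list)


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_divergence(
    seq1: str | np.ndarray,
    seq2: str | np.ndarray,
    code: CodonCode | None = None,
) -> DivergenceEstimate:
    """Nei–Gojobori divergence between two aligned in-frame sequences.

    Site totals are averaged across the two sequences; codons containing
    gaps or ambiguous bases in either sequence are skipped pairwise.
    """
    code = code or STANDARD_CODE
    a = code.encode(seq1) if isinstance(seq1, str) else np.asarray(seq1)
    b = code.encode(seq2) if isinstance(seq2, str) else np.asarray(seq2)
    if a.shape != b.shape:
        raise ValueError("aligned sequences must have equal codon length")
    ok = (a >= 0) & (b >= 0)
    n_comp = int(ok.sum())
    if n_comp == 0:
        raise ValueError("no comparable (ungapped, unambiguous) codon pairs")
    ai, bi = a[ok], b[ok]
    S = 0.5 * (code.syn_sites[ai].sum() + code.syn_sites[bi].sum())
    N = 0.5 * (code.nonsyn_sites[ai].sum() + code.nonsyn_sites[bi].sum())
    Nd = float(code.nd_table[ai, bi].sum())
    Sd = float(code.sd_table[ai, bi].sum())
    pN = Nd / N if N > 0 else 0.0
    pS = Sd / S if S > 0 else 0.0

    flags: list[str] = []
    dN = _jc_correct(pN)
    dS = _jc_correct(pS)
    if dN is None:
        flags.append("dN_saturated")
    if dS is None:
        flags.append("dS_saturated")
    omega: float | None = None
    if dN is not None and dS is not None:
        if dS > 0:
            omega = dN / dS
        else:
            flags.append("omega_undefined_dS_zero")
    else:
        flags.append("omega_undefined_saturation")
    return DivergenceEstimate(
        S_sites=float(S),
        N_sites=float(N),
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        omega=omega,
        n_codons_compared=n_comp,
        flags=flags,
    )


def per_gene_omega(
    sequences: Sequence[str] | Sequence[np.ndarray],
    code: CodonCode | None = None,
) -> DivergenceEstimate:
    """One omega per ortholog alignment: (mean pairwise dN) / (mean pairwise dS).

    A ratio of means over all sequence pairs; pairs with saturated dN or
    dS are dropped from both means. Undefined (flagged) when the mean dS
    is zero or every pair is saturated.
    """
    if len(sequences) < 2:
        raise ValueError("per-gene omega needs at least 2 sequences")
    code = code or STANDARD_CODE
    enc = [code.encode(s) if isinstance(s, str) else np.asarray(s) for s in sequences]
    dns, dss = [], []
    est = None
    n_sat = 0
    for i, j in itertools.combinations(range(len(enc)), 2):
        est = ng86_divergence(enc[i], enc[j], code=code)
        if est.dN is None or est.dS is None:
            n_sat += 1
            continue
        dns.append(est.dN)
        dss.append(est.dS)
    flags: list[str] = []
    if n_sat:
        flags.append(f"{n_sat}_pairs_saturated")
    if not dns:
        return DivergenceEstimate(
            S_sites=math.nan, N_sites=math.nan, Sd=math.nan, Nd=math.nan,
            pS=math.nan, pN=math.nan, dS=None, dN=None, omega=None,
            flags=flags + ["all_pairs_saturated"],
        )
    mean_dn = float(np.mean(dns))
    mean_ds = float(np.mean(dss))
    omega = mean_dn / mean_ds if mean_ds > 0 else None
    if omega is None:
        flags.append("omega_undefined_dS_zero")
    return DivergenceEstimate(
        S_sites=math.nan, N_sites=math.nan, Sd=math.nan, Nd=math.nan,
        pS=math.nan, pN=math.nan,
        dS=mean_ds, dN=mean_dn, omega=omega,
        n_codons_compared=len(enc[0]),
        flags=flags,
    )


def pairwise_dn_table(
    alignments: Mapping[str, Mapping[str, str]],
    pairing: pd.DataFrame,
    min_length_frac: float = 0.5,
    reference: Mapping[str, str] | None = None,
    code: CodonCode | None = None,
) -> pd.DataFrame:
    """dN between every pre-duplication and post-duplication sequence pair.

    Parameters
    ----------
    alignments:
        family -> {sequence_id -> aligned codon sequence}.
    pairing:
        DataFrame with columns ``family, seq_id, species, role, paralog``
        where ``role`` is ``pre`` or ``post`` and ``paralog`` labels the
        post-duplication copy (e.g. ``A``/``B``); ignored for ``pre`` rows.
    min_length_frac:
        sequences whose ungapped length falls below this fraction of the
        family's reference-sequence length are excluded (and logged).
    reference:
        family -> reference sequence id for the length filter; defaults
        to the longest sequence in each family.

    Returns
    -------
    DataFrame with columns ``family, paralog, pre_species, post_species,
    pre_seq, post_seq, dN, dS, omega``.
    """
    code = code or STANDARD_CODE
    required = {"family", "seq_id", "species", "role", "paralog"}
    if not required.issubset(pairing.columns):
        raise ValueError(f"pairing table must have columns {sorted(required)}")
    rows = []
    for family, seqs in alignments.items():
        fam_meta = pairing[pairing["family"] == family]
        if fam_meta.empty:
            logger.warning("family %s has no pairing annotation; skipped", family)
            continue

        def ungapped_len(sid: str) -> int:
            return sum(1 for ch in seqs[sid] if ch not in "-.")

        if reference and family in reference:
            ref_len = ungapped_len(reference[family])
        else:
            ref_len = max(ungapped_len(s) for s in seqs)
        kept = {}
        for sid in seqs:
            if ungapped_len(sid) < min_length_frac * ref_len:
                logger.info(
                    "family %s: sequence %s excluded (shorter than %.0f%% of reference)",
                    family, sid, 100 * min_length_frac,
                )
                continue
            kept[sid] = code.encode(seqs[sid])
        pre = fam_meta[(fam_meta["role"] == "pre") & fam_meta["seq_id"].isin(kept)]
        post = fam_meta[(fam_meta["role"] == "post") & fam_meta["seq_id"].isin(kept)]
        if pre.empty:
            logger.warning("family %s has no usable pre-duplication sequence; skipped", family)
            continue
        for _, prow in pre.iterrows():
            for _, qrow in post.iterrows():
                est = ng86_divergence(kept[prow["seq_id"]], kept[qrow["seq_id"]], code=code)
                rows.append(
                    {
                        "family": family,
                        "paralog": qrow["paralog"],
                        "pre_species": prow["species"],
                        "post_species": qrow["species"],
                        "pre_seq": prow["seq_id"],
                        "post_seq": qrow["seq_id"],
                        "dN": est.dN,
                        "dS": est.dS,
                        "omega": est.omega,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "family", "paralog", "pre_species", "post_species",
            "pre_seq", "post_seq", "dN", "dS", "omega",
        ],
    )


@dataclass
class CliffsDelta:
    """Cliff's delta effect size between two groups of values."""

    delta_signed: float
    delta_magnitude: float
    n: int
    m: int

    @property
    def is_large(self) -> bool:
        return self.delta_magnitude > CLIFF_LARGE_THRESHOLD


def cliffs_delta(values_a: Iterable[float], values_b: Iterable[float]) -> CliffsDelta:
    """Cliff's delta: P(a > b) - P(a < b) over all cross-pairs; ties count 0."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    diff = a[:, None] - b[None, :]
    signed = float((np.sign(diff)).sum() / (a.size * b.size))
    return CliffsDelta(
        delta_signed=signed,
        delta_magnitude=abs(signed),
        n=int(a.size),
        m=int(b.size),
    )
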