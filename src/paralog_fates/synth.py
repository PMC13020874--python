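"""Synthetic data generators with known ground truth.

Three generators cover the three data modalities the pipeline consumes:

* multi-tissue expression profiles for pre-duplication species and for
  paralog pairs in post-duplication species, constructed under one of
  four evolutionary-fate scenarios;
* in-frame codon sequence sets evolved from a common ancestor under a
  controlled dN:dS (omega <= 1, purifying regime);
* gene-family copy-number vectors produced by a known schedule of
  duplication/loss events on a species tree.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .trees import SpeciesTree


class FateName(str, Enum):
    ANCESTRAL_PRESERVED_A = "ANCESTRAL_PRESERVED_A"
    SUBFUNCTIONALIZATION = "SUBFUNCTIONALIZATION"
    HYPOFUNCTIONALIZATION = "HYPOFUNCTIONALIZATION"
    REDUNDANT = "REDUNDANT"


@dataclass
class FateScenario:
    """Generating scenario for one batch of simulated paralog pairs.

    Parameters
    ----------
    name:
        fate category generating the paralog profiles.
    dosage_split:
        share of ancestral expression carried by paralog A under
        HYPOFUNCTIONALIZATION (B carries the complement).
    tissue_mask_A:
        boolean mask of tissues retained by paralog A under
        SUBFUNCTIONALIZATION; B retains the complement, so both paralogs
        together cover all tissues.
    minor_scale:
        residual expression of the minor paralog B under
        ANCESTRAL_PRESERVED_A, as a fraction of the ancestral level.
    noise_sd:
        standard deviation of Gaussian noise added on the
        log2(RPKM + 1) scale to every measured profile.
    """

    name: FateName
    dosage_split: float = 0.5
    tissue_mask_A: np.ndarray | None = None
    minor_scale: float = 0.1
    noise_sd: float = 0.25

    def __post_init__(self) -> None:
        self.name = FateName(self.name)
        if not 0.0 <= self.dosage_split <= 1.0:
            raise ValueError("dosage_split must lie in [0, 1]")
        if not 0.0 <= self.minor_scale <= 1.0:
            raise ValueError("minor_scale must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def paralog_profiles(self, ancestral: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Noise-free RPKM profiles of paralogs A and B given the ancestral one."""
        if self.name is FateName.ANCESTRAL_PRESERVED_A:
            return ancestral.copy(), self.minor_scale * ancestral
        if self.name is FateName.SUBFUNCTIONALIZATION:
            if self.tissue_mask_A is None:
                raise ValueError("SUBFUNCTIONALIZATION requires tissue_mask_A")
            mask = np.asarray(self.tissue_mask_A, dtype=bool)
            if mask.shape != ancestral.shape:
                raise ValueError("tissue_mask_A length must equal the tissue count")
            return ancestral * mask, ancestral * ~mask
        if self.name is FateName.HYPOFUNCTIONALIZATION:
            s = self.dosage_split
            return s * ancestral, (1.0 - s) * ancestral
        return ancestral.copy(), ancestral.copy()  # REDUNDANT


@dataclass
class SimTruth:
    """Ground-truth record attached to every simulated dataset."""

    expression_scenarios: dict[str, str] = field(default_factory=dict)
    codon: dict[str, dict] = field(default_factory=dict)
    copy_number_events: dict[str, list] = field(default_factory=dict)


def default_tissues(n_tissues: int) -> list[str]:
    names = [
        "brain", "cerebellum", "heart", "intestine", "kidney",
        "liver", "ovary", "placenta", "testis",
    ]
    if n_tissues <= len(names):
        return names[:n_tissues]
    return names + [f"tissue{i}" for i in range(len(names), n_tissues)]


def _noisy_rpkm(rpkm: np.ndarray, noise_sd: float, rng: np.random.Generator,
                eps: np.ndarray | None = None) -> np.ndarray:
    """Add Gaussian noise on the log2(RPKM+1) scale; clamp back to RPKM >= 0.

    A precomputed noise vector ``eps`` may be supplied so that two
    profiles measured in the same sample can share their noise.
    """
    if noise_sd == 0 and eps is None:
        return rpkm.copy()
    if eps is None:
        eps = rng.normal(0.0, noise_sd, size=rpkm.shape)
    log2 = np.log2(rpkm + 1.0) + eps
    return np.clip(np.exp2(log2) - 1.0, 0.0, None)


def simulate_expression_pair_set(
    n_pairs: int,
    scenario: FateScenario,
    n_tissues: int = 9,
    pre_species: Sequence[str] = ("prespecies1", "prespecies2"),
    post_species: Sequence[str] = tuple(f"postspecies{i+1}" for i in range(12)),
    ancestral_log2_mean: float = 4.0,
    ancestral_log2_sd: float = 2.0,
    seed: int = 0,
    n_single_copy_families: int = 0,
    gene_length_range: tuple[int, int] = (600, 3000),
    noise_mode: str = "shared",
) -> tuple[ExpressionDataset, SimTruth]:
    """Simulate an RPKM-scale expression dataset of paralog-pair families.

    For each family an ancestral tissue profile is drawn i.i.d. lognormal
    (``2**Normal(ancestral_log2_mean, ancestral_log2_sd)`` per tissue).
    Every pre-duplication species measures that profile plus noise; every
    post-duplication species carries two paralogs constructed from the
    profile according to ``scenario``, plus measurement noise.

    ``noise_mode`` controls how the two paralogs of a family are
    perturbed within one species. The default ``"shared"`` draws one
    log2-scale noise vector per (family, species) and applies it to both
    paralogs, emulating sample-level measurement variation (depth,
    library composition, tissue sampling) that co-measured genes share;
    ``"independent"`` gives each paralog its own draw, adding
    gene-level noise that the paralog total partially averages out.

    Optionally, ``n_single_copy_families`` unduplicated single-copy
    families (one copy in every species) are added as normalization
    anchors.
    """
    if noise_mode not in ("shared", "independent"):
        raise ValueError("noise_mode must be 'shared' or 'independent'")
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    if n_pairs < 1:
        raise ValueError("need at least one simulated pair")
    if ancestral_log2_sd <= 0:
        raise ValueError("ancestral log2-sd must be positive")
    if not pre_species or not post_species:
        raise ValueError("species lists must be non-empty")
    rng = np.random.default_rng(seed)
    tissues = default_tissues(n_tissues)
    all_species = list(pre_species) + list(post_species)

    sample_ids, sample_rows = [], []
    for sp in all_species:
        for t in tissues:
            sample_ids.append(f"{sp}.{t}")
            sample_rows.append({"species": sp, "tissue": t})
    sample_meta = pd.DataFrame(sample_rows, index=pd.Index(sample_ids, name="sample_id"))

    gene_ids: list[str] = []
    gene_rows: list[dict] = []
    data: dict[str, np.ndarray] = {}
    truth = SimTruth()

    def add_gene(gid, species, family, label, length, og, profile):
        gene_ids.append(gid)
        gene_rows.append(
            {
                "species": species,
                "family": family,
                "paralog_label": label,
                "length_bp": int(length),
                "single_copy_og": og,
            }
        )
        data[gid] = profile

    lo, hi = gene_length_range
    for k in range(n_pairs):
        family = f"fam{k:04d}"
        truth.expression_scenarios[family] = scenario.name.value
        ancestral = np.exp2(rng.normal(ancestral_log2_mean, ancestral_log2_sd, n_tissues))
        base_a, base_b = scenario.paralog_profiles(ancestral)
        length = rng.integers(lo, hi)
        for sp in pre_species:
            add_gene(
                f"{family}.{sp}.pre", sp, family, "pre", length, None,
                _noisy_rpkm(ancestral, scenario.noise_sd, rng),
            )
        for sp in post_species:
            eps = None
            if noise_mode == "shared":
                eps = rng.normal(0.0, scenario.noise_sd, n_tissues)
            add_gene(
                f"{family}.{sp}.A", sp, family, "A", length, None,
                _noisy_rpkm(base_a, scenario.noise_sd, rng, eps=eps),
            )
            add_gene(
                f"{family}.{sp}.B", sp, family, "B", length, None,
                _noisy_rpkm(base_b, scenario.noise_sd, rng, eps=eps),
            )

    for k in range(n_single_copy_families):
        og = f"OG{k:04d}"
        ancestral = np.exp2(rng.normal(ancestral_log2_mean, ancestral_log2_sd, n_tissues))
        length = rng.integers(lo, hi)
        for sp in all_species:
            add_gene(
                f"{og}.{sp}", sp, og, "single", length, og,
                _noisy_rpkm(ancestral, scenario.noise_sd, rng),
            )

    gene_index = pd.Index(gene_ids, name="gene_id")
    values = pd.DataFrame(np.nan, index=gene_index, columns=sample_meta.index)
    gene_meta = pd.DataFrame(gene_rows, index=gene_index)
    by_species = {
        sp: [f"{sp}.{t}" for t in tissues] for sp in all_species
    }
    for gid, profile in data.items():
        sp = gene_meta.at[gid, "species"]
        values.loc[gid, by_species[sp]] = profile

    dataset = ExpressionDataset(
        values=values, gene_meta=gene_meta, sample_meta=sample_meta, stage="rpkm"
    )
    return dataset, truth


def simulate_counts_from_expression(
    dataset: ExpressionDataset,
    seed: int = 0,
    lib_size_range: tuple[float, float] = (5e6, 4e7),
    composition_fraction: float = 0.0,
    composition_log2_sd: float = 1.0,
    poisson: bool = True,
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Raw read counts implied by an RPKM-scale dataset, with distortions.

    Per-sample library sizes are drawn log-uniformly from
    ``lib_size_range`` (depth distortion). Optionally a random
    ``composition_fraction`` of genes per species get a species-wide
    multiplicative distortion (lognormal, ``composition_log2_sd`` on the
    log2 scale), emulating composition differences that TMM
    normalization must absorb. Counts are Poisson-sampled around
    RPKM * length_kb * lib_millions (or deterministically rounded with
    ``poisson=False``).

    Returns the raw-counts dataset and a matching "fractional multimap"
    count frame (here identical up to rounding: the simulator does not
    model multimapping artifacts).
    """
    dataset.require_stage("rpkm")
    rng = np.random.default_rng(seed)
    lo, hi = lib_size_range
    libs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(dataset.samples)))
    lib_by_sample = pd.Series(libs, index=dataset.samples)

    rpkm = dataset.values.copy()
    if composition_fraction > 0:
        for sp in dataset.sample_meta["species"].unique():
            sp_samples = dataset.samples_of_species(sp)
            sp_genes = dataset.gene_meta.index[dataset.gene_meta["species"] == sp]
            n_distort = int(round(composition_fraction * len(sp_genes)))
            if n_distort == 0:
                continue
            chosen = rng.choice(sp_genes, size=n_distort, replace=False)
            factors = np.exp2(rng.normal(0.0, composition_log2_sd, size=n_distort))
            rpkm.loc[chosen, sp_samples] = rpkm.loc[chosen, sp_samples].mul(
                factors, axis=0
            )

    length_kb = dataset.gene_meta["length_bp"] / 1000.0
    lam = rpkm.mul(length_kb, axis=0).mul(lib_by_sample / 1e6, axis=1)
    lam_arr = lam.to_numpy()
    mask = np.isnan(lam_arr)
    if poisson:
        counts_arr = rng.poisson(np.where(mask, 0.0, lam_arr)).astype(float)
    else:
        counts_arr = np.round(np.where(mask, 0.0, lam_arr))
    counts_arr[mask] = np.nan
    counts = pd.DataFrame(counts_arr, index=lam.index, columns=lam.columns)
    out = dataset.with_values(counts, "raw_counts")
    return out, counts.copy()


# ---------------------------------------------------------------------------
# codon sequence evolution
# ---------------------------------------------------------------------------

def _codon_machinery():
    from .seqdiv import STANDARD_CODE

    code = STANDARD_CODE
    aa = code.aa  # length-64 array of single letters, '*' for stops
    is_stop = code.is_stop
    sense = np.array([code.index[c] for c in code.sense_codons])
    codon_strings = code.codons
    return aa, is_stop, sense, codon_strings


def _evolve_sequence(
    codons: np.ndarray,
    omega: float,
    n_proposals: int,
    rng: np.random.Generator,
    aa: np.ndarray,
    is_stop: np.ndarray,
) -> np.ndarray:
    """Evolve codon indices by single-nucleotide proposals.

    Proposals are uniform over (codon, position, alternative nucleotide);
    a proposal creating a stop codon is rejected; a synonymous change is
    always accepted; a non-synonymous change is accepted with
    probability omega.
    """
    seq = codons.copy()
    n = len(seq)
    pos_scale = np.array([16, 4, 1])
    positions = rng.integers(0, n, n_proposals)
    codon_pos = rng.integers(0, 3, n_proposals)
    # alternative nucleotide: offset 1..3 from the current one, mod 4
    nt_offsets = rng.integers(1, 4, n_proposals)
    accept_draws = rng.random(n_proposals)
    for i in range(n_proposals):
        p = positions[i]
        old = seq[p]
        scale = pos_scale[codon_pos[i]]
        old_nt = (old // scale) % 4
        new_nt = (old_nt + nt_offsets[i]) % 4
        cand = old + (new_nt - old_nt) * scale
        if is_stop[cand]:
            continue
        if aa[cand] == aa[old] or accept_draws[i] < omega:
            seq[p] = cand
    return seq


def simulate_codon_clade(
    n_codons: int,
    omega: float,
    expected_subs_per_codon: float,
    n_sequences: int,
    seed: int = 0,
) -> tuple[str, list[str], SimTruth]:
    """Evolve ``n_sequences`` descendants of one random ancestor (star tree).

    ``expected_subs_per_codon`` is the expected number of mutation
    proposals per codon on each ancestor-to-descendant branch. Returns
    (ancestor, descendants, truth); sequences are in-frame and contain
    no stop codons.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if omega > 1:
        raise ValueError(
            "omega > 1 (positive selection) is not supported by this simulator"
        )
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    rng = np.random.default_rng(seed)
    aa, is_stop, sense, codon_strings = _codon_machinery()
    ancestor = sense[rng.integers(0, len(sense), n_codons)]

    def decode(ix: np.ndarray) -> str:
        return "".join(codon_strings[i] for i in ix)

    descendants = []
    for _ in range(n_sequences):
        k = int(rng.poisson(n_codons * expected_subs_per_codon))
        descendants.append(decode(_evolve_sequence(ancestor, omega, k, rng, aa, is_stop)))
    truth = SimTruth(codon={"clade": {"omega": omega, "t": expected_subs_per_codon}})
    return decode(ancestor), descendants, truth


def simulate_family_codon_set(
    n_codons: int,
    expected_subs_per_codon: float,
    omega_pre: float,
    omega_a: float,
    omega_b: float,
    pre_species: Sequence[str],
    post_species: Sequence[str],
    seed: int = 0,
    family: str = "family",
) -> tuple[dict[str, str], list[dict]]:
    """One gene family's sequences across pre- and post-duplication species.

    Every sequence evolves independently from a common ancestor (star
    phylogeny): pre-duplication species at ``omega_pre``, paralog A
    copies at ``omega_a`` and paralog B copies at ``omega_b``. Returns a
    {sequence_id: sequence} dict plus pairing-annotation rows suitable
    for :func:`paralog_fates.seqdiv.pairwise_dn_table`.
    """
    rng = np.random.default_rng(seed)
    aa, is_stop, sense, codon_strings = _codon_machinery()
    ancestor = sense[rng.integers(0, len(sense), n_codons)]

    def decode(ix: np.ndarray) -> str:
        return "".join(codon_strings[i] for i in ix)

    def branch(omega: float) -> str:
        k = int(rng.poisson(n_codons * expected_subs_per_codon))
        return decode(_evolve_sequence(ancestor, omega, k, rng, aa, is_stop))

    seqs: dict[str, str] = {}
    rows: list[dict] = []
    for sp in pre_species:
        sid = f"{family}.{sp}.pre"
        seqs[sid] = branch(omega_pre)
        rows.append({"family": family, "seq_id": sid, "species": sp,
                     "role": "pre", "paralog": ""})
    for sp in post_species:
        for label, om in (("A", omega_a), ("B", omega_b)):
            sid = f"{family}.{sp}.{label}"
            seqs[sid] = branch(om)
            rows.append({"family": family, "seq_id": sid, "species": sp,
                         "role": "post", "paralog": label})
    return seqs, rows


def simulate_codon_pairs(
    n_codons: int,
    omega: float,
    expected_subs_per_codon: float,
    n_pairs: int,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], SimTruth]:
    """Simulate independent descendant pairs from independent ancestors."""
    rng = np.random.default_rng(seed)
    pairs = []
    truth = SimTruth()
    for k in range(n_pairs):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        _, (a, b), _ = simulate_codon_clade(
            n_codons, omega, expected_subs_per_codon, 2, seed=sub_seed
        )
        pairs.append((a, b))
        truth.codon[f"pair{k:04d}"] = {"omega": omega, "t": expected_subs_per_codon}
    return pairs, truth


# ---------------------------------------------------------------------------
# copy-number evolution on a species tree
# ---------------------------------------------------------------------------

def simulate_copy_numbers(
    tree: SpeciesTree,
    events: Sequence[tuple[str, str]],
    root_count: int = 1,
    seed: int | None = None,
) -> pd.Series:
    """Leaf copy numbers produced by a duplication/loss schedule.

    ``events`` is a list of (branch_id, "dup" | "loss"); each event
    changes the copy count by +/-1 on that branch, inherited by all
    descendant leaves. A loss on a lineage whose count is already zero
    is rejected. ``seed`` is accepted for API symmetry; the computation
    is deterministic. Returns a Series of counts indexed by leaf id.
    """
    del seed
    if root_count < 0:
        raise ValueError("root_count must be >= 0")
    deltas: dict[str, int] = {}
    for branch, kind in events:
        if branch not in tree or branch == tree.root_id:
            raise ValueError(f"unknown or root branch {branch!r}")
        if kind not in ("dup", "loss"):
            raise ValueError(f"unknown event type {kind!r}")
        deltas[branch] = deltas.get(branch, 0) + (1 if kind == "dup" else -1)

    counts: dict[str, int] = {tree.root_id: root_count}
    for nid in tree.preorder_ids():
        if nid == tree.root_id:
            continue
        parent_count = counts[tree.nodes[nid].parent]
        c = parent_count + deltas.get(nid, 0)
        if c < 0 or (deltas.get(nid, 0) < 0 and parent_count == 0):
            raise ValueError(f"loss on zero-copy lineage at branch {nid!r}")
        counts[nid] = c
    leaves = tree.leaf_ids()
    return pd.Series([counts[l] for l in leaves], index=pd.Index(leaves, name="species"))


def random_event_schedule(
    tree: SpeciesTree,
    n_events: int,
    seed: int,
    root_count: int = 1,
    max_copies: int = 3,
) -> list[tuple[str, str]]:
    """A random feasible duplication/loss schedule on the tree.

    Events are drawn one at a time (uniform branch, uniform type) and
    kept only if the resulting schedule stays feasible: no lineage drops
    below zero copies or exceeds ``max_copies``.
    """
    rng = np.random.default_rng(seed)
    branches = tree.branch_ids()
    events: list[tuple[str, str]] = []
    guard = 0
    while len(events) < n_events and guard < 200 * (n_events + 1):
        guard += 1
        cand = (branches[rng.integers(0, len(branches))],
                "dup" if rng.random() < 0.5 else "loss")
        trial = events + [cand]
        try:
            counts = simulate_copy_numbers(tree, trial, root_count=root_count)
        except ValueError:
            continue
        if (counts > max_copies).any():
            continue
        events = trial
    return events


def simulate_copy_number_matrix(
    tree: SpeciesTree,
    schedules: dict[str, Sequence[tuple[str, str]]],
    root_counts: dict[str, int] | int = 1,
) -> tuple[pd.DataFrame, SimTruth]:
    """Species x family copy-number matrix from per-family event schedules."""
    cols = {}
    truth = SimTruth()
    for family, events in schedules.items():
        rc = root_counts if isinstance(root_counts, int) else root_counts[family]
        cols[family] = simulate_copy_numbers(tree, events, root_count=rc)
        truth.copy_number_events[family] = list(events)
    return pd.DataFrame(cols), truth
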