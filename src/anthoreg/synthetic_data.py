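"""Synthetic multi-omics bundle with planted ground truth.

Emulates the study design the pipeline targets: two fermentation time
points (G2 pre-growth, G8 peak pigment) with three biological replicates
each, one degraded replicate among them, a few hundred toy gene loci with
exon structure on a handful of contigs, long-noncoding transcripts, decoy
transcripts that each violate exactly one lncRNA filter, a flavonoid
metabolite table whose anthocyanin class shows the very large fold
increases characteristic of pigment accumulation (1e2-1e4), and planted
lncRNA -> gene -> metabolite regulatory triples with configurable
correlation strength.

Generation is fully deterministic per seed (the same
:class:`SimulationConfig` reproduces a byte-identical bundle).

Construction notes
------------------
* Counts are negative-binomial around condition-specific means planned on
  the log2-TPM scale; the degraded replicate is drawn around the midpoint
  of the two condition means with strongly inflated log-noise, so pairwise
  sample correlation flags it.
* Decoy transcripts are written with deterministic (rounded-mean) counts so
  their TPM stays inside the band that violates exactly the intended gate.
* Planted regulator lncRNAs and metabolites are built with an exact
  empirical-correlation variant of the shared-component construction
  (``r*z + sqrt(1-r^2)*e`` with ``e`` orthogonalised against ``z``),
  evaluated over the non-degraded samples, so the planted |r| is a property
  of the bundle rather than of sampling luck. The public
  :func:`plant_correlation` keeps the plain stochastic construction.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .lncrna_discovery import TranscriptModel
from .oplsda import MetaboliteTable
from .quantification import compute_tpm

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedBundle",
    "simulate",
    "plant_correlation",
    "DECOY_REASONS",
    "REASON_TO_GATE",
    "PREDICTORS",
]

DECOY_REASONS = (
    "length",
    "expression_single_exon",
    "expression_multi_exon",
    "vote",
    "domain",
)

#: which cascade gate each decoy reason is designed to fail
REASON_TO_GATE = {
    "length": "length",
    "expression_single_exon": "expression",
    "expression_multi_exon": "expression",
    "vote": "vote",
    "domain": "domain",
}

PREDICTORS = ("cpc2", "cnci", "plek", "lgc")

#: anthocyanin pathway roles used to label the curated gene set
PATHWAY_ROLES = (
    "UGTs_1", "DFR_1", "LDOX", "OMT", "CHS_1",
    "F3H_1", "4CL_1", "CHI_1", "PAL_1", "C4H",
)

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
]


@dataclass
class SimulationConfig:
    """All knobs of the simulator; defaults are the emulated study design."""

    seed: int = 0
    n_genes: int = 200
    n_lncrnas: int = 30
    n_decoys_per_reason: int = 2
    n_contigs: int = 4
    contig_length: int = 2_000_000
    n_replicates_per_condition: int = 3
    outlier_replicate: str | None = "G8_2"
    n_planted_regulators: int = 3
    regulator_effect: float = 0.95
    regulator_gene_log2fc: float = 4.0
    n_metabolites: int = 85
    n_anthocyanins: int = 7
    metabolite_de_fraction: float = 0.35
    de_fraction: float = 0.2
    de_log2fc: float = 2.0
    dispersion: float = 0.05
    noise_sd: float = 0.15
    expr_noise_sd: float = 0.25
    outlier_noise_sd: float = 2.0
    vote_error_rate: float = 0.0
    library_size: int = 20_000_000

    def __post_init__(self) -> None:
        def _check(name: str, ok: bool, why: str) -> None:
            if not ok:
                raise ValueError(f"invalid {name}: {why}")

        _check("seed", isinstance(self.seed, (int, np.integer)) and self.seed >= 0,
               f"must be a non-negative integer, got {self.seed!r}")
        for name in ("n_genes", "n_lncrnas", "n_contigs", "contig_length",
                     "n_metabolites", "library_size"):
            _check(name, getattr(self, name) > 0, "must be > 0")
        _check("n_decoys_per_reason", self.n_decoys_per_reason >= 0, "must be >= 0")
        _check("n_contigs", self.n_contigs >= 2,
               "need >= 2 contigs (contig 1 is reserved for the pathway locus)")
        _check("n_replicates_per_condition", self.n_replicates_per_condition >= 2,
               "need >= 2 replicates per condition")
        _check("n_planted_regulators", 0 <= self.n_planted_regulators <= self.n_lncrnas,
               "must satisfy 0 <= n_planted_regulators <= n_lncrnas")
        _check("n_planted_regulators", self.n_planted_regulators <= self.n_anthocyanins,
               "each planted triple needs its own anthocyanin compound")
        _check("n_genes", self.n_genes >= self.n_planted_regulators,
               "need at least one gene per planted regulator")
        _check("n_anthocyanins", 0 <= self.n_anthocyanins <= self.n_metabolites,
               "must satisfy n_anthocyanins <= n_metabolites")
        _check("regulator_effect", 0.7 < self.regulator_effect <= 1.0,
               "target |r| must lie in (0.7, 1.0]")
        for name in ("de_fraction", "metabolite_de_fraction"):
            _check(name, 0.0 <= getattr(self, name) <= 1.0, "must lie in [0, 1]")
        for name in ("dispersion",):
            _check(name, getattr(self, name) >= 0, "must be >= 0")
        for name in ("noise_sd", "expr_noise_sd", "outlier_noise_sd", "de_log2fc",
                     "regulator_gene_log2fc"):
            _check(name, getattr(self, name) > 0, "must be > 0")
        _check("vote_error_rate", 0.0 <= self.vote_error_rate < 0.5,
               "must lie in [0, 0.5)")
        if self.outlier_replicate is not None:
            _check("outlier_replicate", self.outlier_replicate in self.sample_ids,
                   f"must be one of {self.sample_ids} or None")
        needed = 150_000 + self.n_planted_regulators * 300_000 + 150_000 + 5 * 120_000
        _check("contig_length", self.contig_length >= needed,
               f"contig 1 needs >= {needed} bp for {self.n_planted_regulators} "
               "planted loci plus the isolated pathway genes")

    @property
    def sample_ids(self) -> list[str]:
        reps = self.n_replicates_per_condition
        return [f"G2_{i + 1}" for i in range(reps)] + [
            f"G8_{i + 1}" for i in range(reps)
        ]


@dataclass
class GroundTruth:
    """Planted truth against which every downstream stage is scored."""

    de_gene_ids: set[str]
    de_lncrna_ids: set[str]
    true_lncrna_ids: set[str]
    decoy_reasons: dict[str, str]  # decoy id -> violated-filter reason
    regulator_triples: list[tuple[str, str, str, int]]  # (lnc, gene, met, sign)
    de_metabolite_ids: set[str]
    outlier_sample: str | None

    @property
    def decoy_ids(self) -> set[str]:
        return set(self.decoy_reasons)

    def to_dict(self) -> dict:
        return {
            "de_gene_ids": sorted(self.de_gene_ids),
            "de_lncrna_ids": sorted(self.de_lncrna_ids),
            "true_lncrna_ids": sorted(self.true_lncrna_ids),
            "decoy_reasons": dict(sorted(self.decoy_reasons.items())),
            "regulator_triples": [list(t) for t in self.regulator_triples],
            "de_metabolite_ids": sorted(self.de_metabolite_ids),
            "outlier_sample": self.outlier_sample,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            de_gene_ids=set(d["de_gene_ids"]),
            de_lncrna_ids=set(d["de_lncrna_ids"]),
            true_lncrna_ids=set(d["true_lncrna_ids"]),
            decoy_reasons=dict(d["decoy_reasons"]),
            regulator_triples=[tuple(t) for t in d["regulator_triples"]],
            de_metabolite_ids=set(d["de_metabolite_ids"]),
            outlier_sample=d["outlier_sample"],
        )


@dataclass
class SimulatedBundle:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SimulationConfig
    transcripts: list[TranscriptModel]
    sequences: dict[str, str]
    counts: pd.DataFrame
    lengths: pd.Series
    conditions: pd.Series
    calls: pd.DataFrame
    metabolites: MetaboliteTable
    anthocyanin_genes: dict[str, str]
    truth: GroundTruth

    @property
    def gene_models(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.is_known_coding]

    @property
    def noncoding_candidates(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if not t.is_known_coding]


# ---------------------------------------------------------------------------
# correlation planting


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("constant base profile; correlation is undefined")
    return (x - x.mean()) / sd


def plant_correlation(base_profile, target_r: float, seed=None) -> np.ndarray:
    """Shared-component construction of a profile correlated with a base.

    Returns ``target_r * z + sqrt(1 - target_r^2) * eps`` with ``z`` the
    standardized base profile and ``eps`` standardized Gaussian noise; the
    population correlation equals ``target_r``, the realized sample r is
    stochastic (exactly ``+-1`` at ``target_r = +-1``).
    """
    x = np.asarray(base_profile, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("base_profile must be 1-d with >= 3 samples")
    if not -1.0 <= target_r <= 1.0:
        raise ValueError(f"target_r must lie in [-1, 1], got {target_r}")
    z = _standardize(x)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.standard_normal(x.size)
    eps = (eps - eps.mean()) / eps.std()
    return target_r * z + np.sqrt(1.0 - target_r**2) * eps


def _exact_correlated(base: np.ndarray, target_r: float, eps0: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """As :func:`plant_correlation`, but with the noise orthogonalised against
    the standardized base so the *sample* correlation equals ``target_r``
    exactly."""
    z = _standardize(np.asarray(base, dtype=float))
    e = eps0 - eps0.mean()
    e = e - (e @ z) / (z @ z) * z
    if e.std() < 1e-8:  # pathological alignment; retry with fresh noise
        e = rng.standard_normal(z.size)
        e = e - e.mean()
        e = e - (e @ z) / (z @ z) * z
    e = e / e.std()
    return target_r * z + np.sqrt(1.0 - target_r**2) * e


def _balanced_noise(rng: np.random.Generator, groups: list[list[int]], n: int) -> np.ndarray:
    """Zero-group-mean noise pattern whose variance leans on the larger
    replicate group, keeping Welch degrees of freedom healthy in a 3-vs-2
    design."""
    eps = np.zeros(n)
    for idx in groups:
        amp = 1.0 if len(idx) >= 3 else 0.35
        pattern = np.zeros(len(idx))
        pattern[0], pattern[1] = amp, -amp
        rng.shuffle(pattern)
        eps[idx] = pattern * (1.0 if rng.random() < 0.5 else -1.0)
    return eps


def _planted_profile(
    rng: np.random.Generator,
    base: np.ndarray,
    target_r: float,
    groups: list[list[int]],
    max_tries: int = 60,
) -> np.ndarray:
    """Exact-correlation profile that is also clearly condition-separated.

    The planted contract is twofold: the profile's sample correlation with
    ``base`` equals ``target_r`` exactly, and the profile differs between
    the two replicate groups strongly enough that a Welch t-test flags it.
    The noise component leaves the correlation untouched but its random
    placement occasionally concentrates variance in the smaller group,
    collapsing the Welch degrees of freedom; such draws are rejected and the
    noise redrawn (deterministically, from the supplied generator)."""
    best, best_p = None, np.inf
    for _ in range(max_tries):
        y = _exact_correlated(base, target_r, _balanced_noise(rng, groups, base.size), rng)
        a, b = y[groups[0]], y[groups[1]]
        p = stats.ttest_ind(b, a, equal_var=False).pvalue
        delta = abs(b.mean() - a.mean())
        if p <= 0.02 and delta >= 1.0:
            return y
        if p < best_p:
            best, best_p = y, p
    return best


# ---------------------------------------------------------------------------
# structural helpers


def _partition(rng: np.random.Generator, total: int, parts: int, minimum: int) -> list[int]:
    parts = max(1, min(parts, total // max(minimum, 1)))
    lens = np.full(parts, minimum, dtype=int)
    extra = total - minimum * parts
    if extra > 0 and parts > 1:
        w = rng.random(parts)
        add = np.floor(extra * w / w.sum()).astype(int)
        add[-1] += extra - add.sum()
        lens += add
    elif extra > 0:
        lens[0] += extra
    return lens.tolist()


def _make_exons(rng: np.random.Generator, start: int, total_len: int,
                n_exons: int) -> tuple[tuple[int, int], ...]:
    lens = _partition(rng, total_len, n_exons, 30)
    exons = []
    pos = start
    for i, ln in enumerate(lens):
        exons.append((pos, pos + ln - 1))
        if i < len(lens) - 1:
            pos += ln + int(rng.integers(60, 400))
    return tuple(exons)


def _coding_seq(rng: np.random.Generator, length: int) -> str:
    ncod = max(0, length // 3 - 2)
    idx = rng.integers(0, len(_CODONS), size=ncod)
    body = "".join(_CODONS[i] for i in idx)
    seq = "ATG" + body + "TAA"
    pad = length - len(seq)
    if pad > 0:
        seq += "".join("ACGT"[i] for i in rng.integers(0, 4, size=pad))
    return seq[:length]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


# ---------------------------------------------------------------------------
# the simulator


def simulate(config: SimulationConfig) -> SimulatedBundle:
    """Generate the full toy multi-omics bundle for one seed.

    See the module docstring for the generative model. Identical configs
    produce identical bundles.
    """
    cfg = config
    children = np.random.SeedSequence(cfg.seed).spawn(7)
    r_layout, r_expr, r_counts, r_met, r_seq, r_plant, r_votes = (
        np.random.default_rng(c) for c in children
    )

    samples = cfg.sample_ids
    reps = cfg.n_replicates_per_condition
    conditions = pd.Series(
        ["G2"] * reps + ["G8"] * reps, index=samples, name="condition"
    )
    outlier = cfg.outlier_replicate
    retained = [s for s in samples if s != outlier]
    cond_sign = np.array([1.0 if conditions[s] == "G8" else -1.0 for s in samples])

    contig_name = [f"contig_{i + 1}" for i in range(cfg.n_contigs)]

    transcripts: dict[str, TranscriptModel] = {}
    anth_genes: dict[str, str] = {}
    planted: list[dict] = []

    # --- planted regulator loci on contig 1, >=300 kb apart so no lncRNA
    # falls inside the 100 kb window of another triple's gene
    gene_no = 0
    for i in range(cfg.n_planted_regulators):
        anchor = 150_000 + i * 300_000
        gene_no += 1
        gid = f"GENE{gene_no:04d}"
        glen = int(r_layout.integers(900, 2400))
        gexons = _make_exons(r_layout, anchor, glen, int(r_layout.integers(2, 5)))
        transcripts[gid] = TranscriptModel(
            gid, contig_name[0], "+" if r_layout.random() < 0.5 else "-",
            gexons, is_known_coding=True,
            has_known_domain=bool(r_layout.random() < 0.7),
        )
        lid = f"LNC{i + 1:03d}"
        gap = int(r_layout.integers(15_000, 45_000))
        llen = int(r_layout.integers(400, 1200))
        lexons = _make_exons(r_layout, gexons[-1][1] + gap, llen, 2)
        transcripts[lid] = TranscriptModel(
            lid, contig_name[0], "+" if r_layout.random() < 0.5 else "-", lexons
        )
        anth_genes[gid] = PATHWAY_ROLES[i % len(PATHWAY_ROLES)]
        planted.append(
            {"lnc": lid, "gene": gid, "sign": -1 if r_layout.random() < 0.5 else 1}
        )

    # --- isolated extra pathway genes on contig 1 (no lncRNA within 100 kb)
    extra_base = 150_000 + cfg.n_planted_regulators * 300_000 + 150_000
    n_extra = min(5, cfg.n_genes - cfg.n_planted_regulators)
    for j in range(n_extra):
        gene_no += 1
        gid = f"GENE{gene_no:04d}"
        glen = int(r_layout.integers(600, 3000))
        gexons = _make_exons(
            r_layout, extra_base + j * 120_000, glen, int(r_layout.integers(1, 6))
        )
        transcripts[gid] = TranscriptModel(
            gid, contig_name[0], "+" if r_layout.random() < 0.5 else "-",
            gexons, is_known_coding=True,
            has_known_domain=bool(r_layout.random() < 0.7),
        )
        anth_genes[gid] = PATHWAY_ROLES[
            (cfg.n_planted_regulators + j) % len(PATHWAY_ROLES)
        ]

    def _random_locus(total_len: int, n_exons: int) -> tuple[str, tuple]:
        c = int(r_layout.integers(1, cfg.n_contigs))
        span_budget = total_len + (n_exons - 1) * 400 + 2000
        start = int(r_layout.integers(1000, cfg.contig_length - span_budget))
        return contig_name[c], _make_exons(r_layout, start, total_len, n_exons)

    # --- background genes and lncRNAs on contigs 2..n
    while gene_no < cfg.n_genes:
        gene_no += 1
        gid = f"GENE{gene_no:04d}"
        ctg, exons = _random_locus(
            int(r_layout.integers(600, 3000)), int(r_layout.integers(1, 6))
        )
        transcripts[gid] = TranscriptModel(
            gid, ctg, "+" if r_layout.random() < 0.5 else "-", exons,
            is_known_coding=True, has_known_domain=bool(r_layout.random() < 0.7),
        )
    for i in range(cfg.n_planted_regulators, cfg.n_lncrnas):
        lid = f"LNC{i + 1:03d}"
        ctg, exons = _random_locus(
            int(r_layout.integers(300, 2000)), int(r_layout.integers(1, 4))
        )
        transcripts[lid] = TranscriptModel(
            lid, ctg, "+" if r_layout.random() < 0.5 else "-", exons
        )

    # --- decoys, each designed to violate exactly one cascade gate
    decoy_reasons: dict[str, str] = {}
    for reason in DECOY_REASONS:
        for k in range(cfg.n_decoys_per_reason):
            did = f"DECOY_{reason}_{k + 1}"
            if reason == "length":
                total, n_exons = int(r_layout.integers(120, 200)), 2
            elif reason == "expression_single_exon":
                total, n_exons = int(r_layout.integers(300, 1500)), 1
            elif reason == "expression_multi_exon":
                total, n_exons = int(r_layout.integers(300, 1500)), int(r_layout.integers(2, 4))
            else:  # vote, domain
                total, n_exons = int(r_layout.integers(300, 1500)), int(r_layout.integers(1, 4))
            ctg, exons = _random_locus(total, n_exons)
            transcripts[did] = TranscriptModel(
                did, ctg, "+" if r_layout.random() < 0.5 else "-", exons,
                has_known_domain=(reason == "domain"),
            )
            decoy_reasons[did] = reason

    gene_ids = [t for t in transcripts if t.startswith("GENE")]
    lnc_ids = [t for t in transcripts if t.startswith("LNC")]
    decoy_ids = list(decoy_reasons)
    planted_lnc = {p["lnc"] for p in planted}
    planted_gene = {p["gene"] for p in planted}
    all_ids = gene_ids + lnc_ids + decoy_ids
    lengths = pd.Series({i: transcripts[i].length for i in all_ids}, name="length")

    # --- planned expression (log2 relative-TPM scale) for genes and lncRNAs
    regular_ids = gene_ids + lnc_ids
    mu = np.concatenate([
        r_expr.uniform(2.5, 9.5, size=len(gene_ids)),
        r_expr.uniform(4.0, 7.5, size=len(lnc_ids)),
    ])
    eff = np.zeros(len(regular_ids))
    de_draw = r_expr.random(len(regular_ids))
    de_sign = np.where(r_expr.random(len(regular_ids)) < 0.5, -1.0, 1.0)
    for j, fid in enumerate(regular_ids):
        if fid in planted_gene:
            eff[j] = cfg.regulator_gene_log2fc  # pathway genes induced at G8
        elif fid in planted_lnc:
            eff[j] = 0.0  # provisional; replaced by the planting pass
        elif de_draw[j] < cfg.de_fraction:
            eff[j] = de_sign[j] * cfg.de_log2fc
    de_gene_ids = {f for f, e in zip(regular_ids, eff) if e != 0 and f.startswith("GENE")}
    de_lnc_ids = {f for f, e in zip(regular_ids, eff) if e != 0 and f.startswith("LNC")}

    L = np.empty((len(regular_ids), len(samples)))
    for si, s in enumerate(samples):
        if s == outlier:
            # midpoint of the two condition means + inflated noise: the
            # degraded replicate drifts toward the other condition
            L[:, si] = mu + r_expr.normal(0.0, cfg.outlier_noise_sd, len(regular_ids))
        else:
            L[:, si] = (
                mu + eff / 2.0 * cond_sign[si]
                + r_expr.normal(0.0, cfg.expr_noise_sd, len(regular_ids))
            )

    # decoy TPM targets, in actual TPM units (bands sit safely inside the
    # violated gate even after count rounding)
    bands = {
        "length": (4.0, 12.0),
        "expression_single_exon": (0.9, 1.6),
        "expression_multi_exon": (0.15, 0.35),
        "vote": (4.0, 12.0),
        "domain": (4.0, 12.0),
    }
    decoy_tpm = np.empty((len(decoy_ids), len(samples)))
    for di, did in enumerate(decoy_ids):
        lo, hi = bands[decoy_reasons[did]]
        decoy_tpm[di] = r_expr.uniform(lo, hi, size=len(samples))

    # per-sample normalisation so planned values are actual TPM
    reg_tpm = 2.0**L
    alpha = (1.0e6 - decoy_tpm.sum(axis=0)) / reg_tpm.sum(axis=0)
    tpm_plan = np.vstack([reg_tpm * alpha, decoy_tpm])
    tpm_plan = pd.DataFrame(tpm_plan, index=all_ids, columns=samples)

    # --- counts
    lib = cfg.library_size * np.exp(r_counts.normal(0.0, 0.05, size=len(samples)))
    rate = tpm_plan.mul(lengths, axis=0)
    mean_counts = rate.div(rate.sum(axis=0), axis=1).mul(lib, axis=1)
    deterministic = set(decoy_ids) | planted_lnc
    stoch_ids = [f for f in all_ids if f not in deterministic]
    mc_stoch = mean_counts.loc[stoch_ids].to_numpy()
    if cfg.dispersion > 0:
        n_param = 1.0 / cfg.dispersion
        p_param = n_param / (n_param + mc_stoch)
        drawn = r_counts.negative_binomial(n_param, p_param)
    else:
        drawn = r_counts.poisson(mc_stoch)
    counts = mean_counts.round().astype(np.int64)
    counts.loc[stoch_ids] = drawn

    # --- planting pass: exact-correlation lncRNA profiles against realized
    # target-gene expression over the non-degraded samples
    ret_pos = [samples.index(s) for s in retained]
    groups = [
        [i for i, s in enumerate(retained) if conditions[s] == "G2"],
        [i for i, s in enumerate(retained) if conditions[s] == "G8"],
    ]
    logt = np.log2(compute_tpm(counts, lengths) + 1.0)
    background_lnc = [l for l in lnc_ids if l not in planted_lnc]
    lnc_level = float(logt.loc[background_lnc].to_numpy().mean()) if background_lnc else 8.0
    s_rate = (counts.div(lengths, axis=0)).sum(axis=0)

    for entry in planted:
        g = logt.loc[entry["gene"], retained].to_numpy()
        y = _planted_profile(
            r_plant, g, entry["sign"] * cfg.regulator_effect, groups
        )
        level = lnc_level + r_plant.normal(0.0, 0.3)
        l_ret = level + g.std() * y
        tpm_l = np.maximum(2.0**l_ret - 1.0, 0.0)
        llen = lengths[entry["lnc"]]
        c_ret = np.round(tpm_l * llen * s_rate[retained].to_numpy() / 1.0e6)
        counts.loc[entry["lnc"], retained] = c_ret.astype(np.int64)
        if outlier is not None:
            l_out = level + r_plant.normal(0.0, 0.5)
            c_out = round((2.0**l_out - 1.0) * llen * s_rate[outlier] / 1.0e6)
            counts.loc[entry["lnc"], outlier] = int(c_out)
    de_lnc_ids |= planted_lnc
    logt = np.log2(compute_tpm(counts, lengths) + 1.0)

    # --- metabolites
    class_template = (
        ["flavonol"] * 17 + ["isoflavone"] * 10 + ["flavanone"] * 8 + ["polyphenol"] * 6
    )
    n_other = cfg.n_metabolites - cfg.n_anthocyanins
    other_classes = (class_template + ["other_flavone"] * n_other)[:n_other]
    met_classes = ["anthocyanin"] * cfg.n_anthocyanins + other_classes
    met_ids = [f"MET{i + 1:04d}" for i in range(cfg.n_metabolites)]
    classes = pd.Series(met_classes, index=met_ids, name="compound_class")

    mu_m = r_met.uniform(14.0, 24.0, size=cfg.n_metabolites)
    eff_m = np.zeros(cfg.n_metabolites)
    # anthocyanins: very large increases at G8 (1e2-1e4 fold)
    eff_m[: cfg.n_anthocyanins] = r_met.uniform(9.0, 13.3, size=cfg.n_anthocyanins)
    dm_draw = r_met.random(cfg.n_metabolites)
    dm_sign = np.where(r_met.random(cfg.n_metabolites) < 0.5, -1.0, 1.0)
    for j in range(cfg.n_anthocyanins, cfg.n_metabolites):
        if dm_draw[j] < cfg.metabolite_de_fraction:
            eff_m[j] = dm_sign[j] * r_met.uniform(1.5, 4.0)
    M = np.empty((cfg.n_metabolites, len(samples)))
    for si in range(len(samples)):
        M[:, si] = (
            mu_m + eff_m / 2.0 * cond_sign[si]
            + r_met.normal(0.0, cfg.noise_sd, cfg.n_metabolites)
        )

    triples: list[tuple[str, str, str, int]] = []
    for i, entry in enumerate(planted):
        met_id = met_ids[i]  # one dedicated anthocyanin compound per triple
        lnc_log = logt.loc[entry["lnc"], retained].to_numpy()
        target_fc = float(r_met.uniform(9.0, 13.0))
        g2_all = [si for si, s in enumerate(samples) if conditions[s] == "G2"]
        g8_all = [si for si, s in enumerate(samples) if conditions[s] == "G8"]
        row = None
        # the planted compound must survive the 3-vs-3 screen as well as
        # carry the exact lncRNA correlation over the retained samples;
        # redraw the noise placement until the full-row Welch test is clear
        for _ in range(60):
            y = _exact_correlated(
                lnc_log,
                entry["sign"] * cfg.regulator_effect,
                _balanced_noise(r_plant, groups, len(retained)),
                r_plant,
            )
            dy = y[groups[1]].mean() - y[groups[0]].mean()
            b_m = target_fc / dy
            a_m = 15.0 - b_m * y[groups[0]].mean()
            cand = np.empty(len(samples))
            cand[ret_pos] = a_m + b_m * y
            if outlier is not None:
                oi = samples.index(outlier)
                own = 1 if conditions[outlier] == "G8" else 0
                cand[oi] = (
                    a_m + b_m * y[groups[own]].mean()
                    + r_met.normal(0.0, cfg.noise_sd)
                )
            p_full = stats.ttest_ind(
                cand[g8_all], cand[g2_all], equal_var=False
            ).pvalue
            if row is None or p_full < best_p:
                row, best_p = cand, p_full
            if p_full <= 0.005:
                break
        M[i] = row
        triples.append((entry["lnc"], entry["gene"], met_id, entry["sign"]))
    metabolites = MetaboliteTable(
        abundances=pd.DataFrame(2.0**M, index=met_ids, columns=samples),
        classes=classes,
        conditions=conditions.copy(),
    )
    de_met_ids = {m for m, e in zip(met_ids, eff_m) if e != 0}

    # --- predictor calls and sequences
    calls = pd.DataFrame("noncoding", index=all_ids, columns=list(PREDICTORS))
    calls.loc[gene_ids] = "coding"
    for did in decoy_ids:
        if decoy_reasons[did] == "vote":
            keep = int(r_votes.integers(0, len(PREDICTORS)))
            row = ["coding"] * len(PREDICTORS)
            row[keep] = "noncoding"  # a single noncoding vote: below quorum
            calls.loc[did] = row
    if cfg.vote_error_rate > 0:
        flip = r_votes.random(calls.shape) < cfg.vote_error_rate
        flipped = calls.to_numpy(dtype=object)
        swap = {"coding": "noncoding", "noncoding": "coding"}
        for i, j in zip(*np.nonzero(flip)):
            flipped[i, j] = swap[flipped[i, j]]
        calls = pd.DataFrame(flipped, index=calls.index, columns=calls.columns)

    sequences = {}
    for fid in all_ids:
        n = int(lengths[fid])
        sequences[fid] = (
            _coding_seq(r_seq, n) if fid.startswith("GENE") else _random_seq(r_seq, n)
        )

    truth = GroundTruth(
        de_gene_ids=de_gene_ids,
        de_lncrna_ids=de_lnc_ids,
        true_lncrna_ids=set(lnc_ids),
        decoy_reasons=decoy_reasons,
        regulator_triples=triples,
        de_metabolite_ids=de_met_ids | {t[2] for t in triples},
        outlier_sample=outlier,
    )
    return SimulatedBundle(
        config=cfg,
        transcripts=[transcripts[i] for i in all_ids],
        sequences=sequences,
        counts=counts,
        lengths=lengths,
        conditions=conditions,
        calls=calls,
        metabolites=metabolites,
        anthocyanin_genes=anth_genes,
        truth=truth,
    )
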