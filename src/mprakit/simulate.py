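"""Negative-binomial simulation of barcode-level MPRA count data.

Synthetic datasets carry a known ground truth and mirror the statistical
structure of real barcode count tables: overdispersed counts per barcode,
a variant-specific number of barcodes, technical replicates generated in
pairs from shared base templates, five variant effect groups at log2 fold
changes {-2, -0.5, 0, 0.5, 2} (alternative-allele RNA means scaled by
{0.25, 1/sqrt(2), 1, sqrt(2), 4}), and an optional multiplicative RNA
outlier process.

Counts are drawn NB(n, p) with the method-of-moments parameterization

    n = mu^2 / (sigma^2 - mu),    p = n / (n + mu)

which has mean mu and variance sigma^2 (requires sigma^2 > mu).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import BarcodeCountTable, VariantMap

__all__ = [
    "EFFECT_GROUPS",
    "SimulationSpec",
    "OutlierConfig",
    "nb_params",
    "make_templates",
    "simulate_dataset",
    "inject_outliers",
]

#: group label -> true log2 fold change of the alternative allele
EFFECT_GROUPS: tuple[tuple[str, float], ...] = (
    ("strong_repressing", -2.0),
    ("weak_repressing", -0.5),
    ("neutral", 0.0),
    ("weak_activating", 0.5),
    ("strong_activating", 2.0),
)

DEFAULT_HIT_PROBS = (0.85, 0.05, 0.04, 0.03, 0.02, 0.01)


def nb_params(mu: float, var: float) -> tuple[float, float]:
    """Method-of-moments NB parameters (n, p) for mean ``mu``, variance ``var``.

    Raises ``ValueError`` unless ``var > mu > 0`` (the NB requires
    overdispersion).  The implied mean n(1-p)/p equals ``mu`` exactly.
    """
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    if np.any(mu <= 0) or np.any(var <= mu):
        raise ValueError("NB parameterization requires var > mu > 0")
    n = mu**2 / (var - mu)
    p = n / (n + mu)
    return (float(n), float(p)) if n.ndim == 0 else (n, p)


@dataclass
class Templates:
    """Per-variant NB parameter templates, one set per base replicate."""

    mu_dna: np.ndarray   # (n_variants, n_base_replicates)
    var_dna: np.ndarray
    mu_rna: np.ndarray
    var_rna: np.ndarray
    n_barcodes: np.ndarray  # (n_variants,), shared between ref and alt

    def __post_init__(self):
        if np.any(self.var_dna <= self.mu_dna) or np.any(self.var_rna <= self.mu_rna):
            raise ValueError("templates require sigma^2 > mu (overdispersion)")
        if np.any(self.n_barcodes < 10):
            raise ValueError("templates require >= 10 barcodes per variant")


def make_templates(n_variants: int, rng: np.random.Generator,
                   mu_range: tuple[float, float] = (20.0, 500.0),
                   dispersion_range: tuple[float, float] = (1.5, 10.0),
                   barcode_range: tuple[int, int] = (10, 60),
                   replicate_sd: float = 0.3,
                   n_base_replicates: int = 3) -> Templates:
    """Sample plausible (mu, sigma^2, N) templates.

    Each variant gets one characteristic DNA and RNA abundance, log-uniform
    on ``mu_range``; per-replicate means vary around it by a log-normal
    technical factor with log-scale SD ``replicate_sd`` (~±35% by default),
    mirroring how a real sequence's empirical per-replicate moments are
    strongly correlated across technical replicates.  Variances are
    ``phi * mu`` with the dispersion factor phi log-uniform on
    ``dispersion_range`` (per variant/replicate/channel); the number of
    barcodes is uniform on ``barcode_range`` (inclusive).
    """
    shape = (n_variants, n_base_replicates)

    def _logu(lo, hi, size):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))

    base_dna = _logu(*mu_range, (n_variants, 1))
    base_rna = _logu(*mu_range, (n_variants, 1))
    mu_dna = base_dna * np.exp(rng.normal(0.0, replicate_sd, shape))
    mu_rna = base_rna * np.exp(rng.normal(0.0, replicate_sd, shape))
    phi_dna = _logu(*dispersion_range, shape)
    phi_rna = _logu(*dispersion_range, shape)
    n_bc = rng.integers(barcode_range[0], barcode_range[1] + 1, size=n_variants)
    return Templates(mu_dna=mu_dna, var_dna=phi_dna * mu_dna,
                     mu_rna=mu_rna, var_rna=phi_rna * mu_rna, n_barcodes=n_bc)


@dataclass
class SimulationSpec:
    """Study conditions for a simulated variant MPRA dataset.

    Defaults are the benchmark conditions: 5000 variants split equally
    over the five effect groups, three base replicate templates each
    duplicated twice for six technical replicates.
    """

    n_variants: int = 5000
    replicate_duplication: int = 2
    n_base_replicates: int = 3
    seed: int = 0
    templates: Templates | None = None
    effect_groups: tuple[tuple[str, float], ...] = EFFECT_GROUPS

    def __post_init__(self):
        if self.n_variants % len(self.effect_groups) != 0:
            raise ValueError("n_variants must divide evenly into effect groups")

    @property
    def n_replicates(self) -> int:
        return self.n_base_replicates * self.replicate_duplication


@dataclass
class OutlierConfig:
    """Multiplicative RNA outlier process.

    A random ``fraction`` of barcodes is hit; for each, the number of
    affected replicates k is drawn from ``replicate_hit_probs`` and the RNA
    count in k uniformly chosen replicates is multiplied by ``multiplier``.
    """

    fraction: float
    multiplier: float = 25.0
    replicate_hit_probs: tuple[float, ...] = DEFAULT_HIT_PROBS
    n_repetitions: int = 5
    seed: int = 0

    def __post_init__(self):
        probs = np.asarray(self.replicate_hit_probs, dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("replicate_hit_probs must sum to 1")
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("fraction must be in (0, 1]")
        if self.multiplier <= 1.0:
            raise ValueError("multiplier must exceed 1")


# ----------------------------------------------------------------------
def _random_barcodes(n: int, rng: np.random.Generator, length: int = 16) -> np.ndarray:
    """n globally unique random DNA strings of the given length."""
    letters = np.array(list("ACGT"))
    out = np.empty(n, dtype=f"U{length}")
    todo = np.arange(n)
    while len(todo):
        codes = rng.integers(0, 4, size=(len(todo), length))
        out[todo] = np.ascontiguousarray(letters[codes]).view(f"U{length}").ravel()
        dup = pd.Index(out).duplicated()
        todo = np.nonzero(dup)[0]
    return out


def _draw_counts(rng, mu_vr, var_vr, n_bc):
    """NB draws for all (variant, replicate, barcode) cells.

    ``mu_vr``/``var_vr`` have shape (n_variants, n_replicates); output is a
    flat array ordered variant-major, replicate, then barcode.
    """
    reps_per_variant = np.repeat(n_bc, mu_vr.shape[1])
    mu = np.repeat(mu_vr.reshape(-1), reps_per_variant)
    var = np.repeat(var_vr.reshape(-1), reps_per_variant)
    n = mu**2 / (var - mu)
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_dataset(spec: SimulationSpec) -> tuple[BarcodeCountTable, pd.DataFrame, VariantMap]:
    """Simulate a barcode count table with known variant effects.

    Returns ``(counts, truth, variant_map)`` where ``truth`` has columns
    variant_id, group, true_logfc.  Reference and alternative DNA counts
    are identically distributed; alternative RNA is drawn with the
    reference RNA mean scaled by 2**logFC, preserving the template's
    dispersion factor at the scaled mean.  Bit-reproducible given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    nv = spec.n_variants
    templates = spec.templates
    if templates is None:
        templates = make_templates(nv, rng, n_base_replicates=spec.n_base_replicates)

    n_reps = spec.n_replicates
    dup = spec.replicate_duplication
    # expand base templates to replicates: replicate r uses template r // dup
    mu_dna = np.repeat(templates.mu_dna, dup, axis=1)
    var_dna = np.repeat(templates.var_dna, dup, axis=1)
    mu_rna = np.repeat(templates.mu_rna, dup, axis=1)
    var_rna = np.repeat(templates.var_rna, dup, axis=1)
    n_bc = templates.n_barcodes

    groups = np.repeat([g for g, _ in spec.effect_groups], nv // len(spec.effect_groups))
    logfc = np.repeat([f for _, f in spec.effect_groups], nv // len(spec.effect_groups))
    mult = 2.0 ** logfc
    phi_rna = var_rna / mu_rna
    mu_rna_alt = mu_rna * mult[:, None]
    var_rna_alt = phi_rna * mu_rna_alt

    variant_ids = np.array([f"var{i + 1:05d}" for i in range(nv)])
    total_bc = int(n_bc.sum())
    all_bcs = _random_barcodes(2 * total_bc, rng)
    bc_ref, bc_alt = all_bcs[:total_bc], all_bcs[total_bc:]

    # record layout per allele: variant-major, then replicate, then barcode
    rows_per_variant = n_reps * n_bc
    total_rows = int(rows_per_variant.sum())
    row_start = np.concatenate([[0], np.cumsum(rows_per_variant)[:-1]])
    bc_start = np.concatenate([[0], np.cumsum(n_bc)[:-1]])
    q = np.arange(total_rows) - np.repeat(row_start, rows_per_variant)
    n_long = np.repeat(n_bc, rows_per_variant)
    bc_idx = np.repeat(bc_start, rows_per_variant) + q % n_long

    rep_names = np.array([f"rep{r + 1}" for r in range(n_reps)])
    replicate = np.repeat(np.tile(rep_names, nv), np.repeat(n_bc, n_reps))

    parts = []
    for suffix, bcs, mu_r, var_r in (("ref", bc_ref, mu_rna, var_rna),
                                     ("alt", bc_alt, mu_rna_alt, var_rna_alt)):
        dna = _draw_counts(rng, mu_dna, var_dna, n_bc)
        rna = _draw_counts(rng, mu_r, var_r, n_bc)
        parts.append(pd.DataFrame({
            "replicate": replicate,
            "barcode": bcs[bc_idx],
            "oligo": np.repeat(np.char.add(variant_ids, f"_{suffix}"), rows_per_variant),
            "dna_count": dna.astype(np.int64),
            "rna_count": rna.astype(np.int64),
        }))
    counts = BarcodeCountTable.from_frame(pd.concat(parts, ignore_index=True),
                                          validate=False)
    truth = pd.DataFrame({"variant_id": variant_ids, "group": groups,
                          "true_logfc": logfc})
    vmap = VariantMap.from_frame(pd.DataFrame({
        "variant_id": variant_ids,
        "ref_oligo": np.char.add(variant_ids, "_ref"),
        "alt_oligo": np.char.add(variant_ids, "_alt"),
    }))
    return counts, truth, vmap


def inject_outliers(counts: BarcodeCountTable,
                    cfg: OutlierConfig) -> tuple[BarcodeCountTable, pd.DataFrame]:
    """Multiply RNA counts of a random barcode subset in random replicates.

    Returns the modified table and a registry of every changed cell
    (columns barcode, oligo, replicate, rna_before, rna_after).
    """
    reps = counts.replicates
    n_reps = len(reps)
    probs = np.asarray(cfg.replicate_hit_probs, dtype=float)
    if len(probs) != n_reps:
        raise ValueError(f"replicate_hit_probs has length {len(probs)} "
                         f"but the table has {n_reps} replicates")
    rng = np.random.default_rng(cfg.seed)
    barcodes = np.sort(counts.df["barcode"].unique())
    n_out = int(round(cfg.fraction * len(barcodes)))
    empty = pd.DataFrame(columns=["barcode", "oligo", "replicate",
                                  "rna_before", "rna_after"])
    if n_out == 0:
        return counts, empty

    hit_bcs = barcodes[rng.choice(len(barcodes), size=n_out, replace=False)]
    k = rng.choice(np.arange(1, n_reps + 1), size=n_out, p=probs)
    # k distinct replicates per barcode, uniformly: rank random keys
    ranks = np.argsort(np.argsort(rng.random((n_out, n_reps)), axis=1), axis=1)
    sel = ranks < k[:, None]
    pair_bc, pair_rep = np.nonzero(sel)
    pairs = pd.DataFrame({"barcode": hit_bcs[pair_bc],
                          "replicate": np.array(reps)[pair_rep], "_hit": True})

    df = counts.df.merge(pairs, on=["barcode", "replicate"], how="left")
    hit = df["_hit"].notna()
    before = df.loc[hit, "rna_count"].to_numpy()
    after = np.round(cfg.multiplier * before).astype(np.int64)
    df.loc[hit, "rna_count"] = after
    registry = pd.DataFrame({
        "barcode": df.loc[hit, "barcode"].to_numpy(),
        "oligo": df.loc[hit, "oligo"].to_numpy(),
        "replicate": df.loc[hit, "replicate"].to_numpy(),
        "rna_before": before,
        "rna_after": after,
    })
    out = BarcodeCountTable.from_frame(df.drop(columns="_hit"), validate=False)
    return out, registry
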