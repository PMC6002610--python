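"""Synthetic RNA-seq experiment emulating a paired enrichment study design.

The generator reproduces the statistical structure the downstream analysis
assumes: six litters each contributing one environmentally enriched (EE) and
one barren-housed (B) male piglet per cull timepoint (1 h and 4 h), i.e.
``n_litters x 2 treatments x 2 timepoints`` frontal-cortex samples; gene-level
negative-binomial counts with log-uniform baseline abundances; a per-(litter,
gene) random effect shared by all samples of a litter; a transient
immediate-early-gene (IEG) induction in EE animals at 1 h only; and a
persistent microglial-signature depression in EE animals at both timepoints.
Gene lengths are drawn so that TPM and CPM genuinely differ.

Counts for gene g in sample j are NB with mean

    mu_gj = L_j * w_g * exp(u_{l(j),g}) * 2^{delta_g(treatment_j, time_j)} / sum_g w_g

where w_g = exp(baseline ln-mean), u is the litter effect and delta the
injected log2 treatment effect, so the expected EE/B mean ratio for an
affected gene is exactly 2^delta (litter effects are shared within litters
and cancel in expectation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSignature, SampleTable

log = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults give a 2,000-gene desk-scale version of a ~22,000-gene brain
    dataset; signature sizes are the study-scale 123 IEG / 569 microglial
    sets scaled by the same ratio. ``litter_sd`` and
    ``baseline_log_mean_range`` are on the natural-log scale;
    ``nb_dispersion`` is the NB dispersion phi (variance = mu + phi*mu^2).
    """

    n_genes: int = 2000
    n_litters: int = 6
    timepoints: Sequence[str] = ("1h", "4h")
    treatments: Sequence[str] = ("EE", "B")
    baseline_log_mean_range: tuple[float, float] = (1.0, 7.0)
    nb_dispersion: float = 0.05
    litter_sd: float = 0.15
    ieg_genes: int = 11
    ieg_log2fc: float = 1.0
    microglia_genes: int = 52
    microglia_log2fc: float = -1.0
    library_size_range: tuple[int, int] = (4_000_000, 8_000_000)
    gene_length_range: tuple[float, float] = (500.0, 10_000.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_litters < 1:
            raise ValueError("n_genes and n_litters must be positive")
        if self.ieg_genes < 0 or self.microglia_genes < 0:
            raise ValueError("signature gene counts must be non-negative")
        if self.ieg_genes + self.microglia_genes > self.n_genes:
            raise ValueError("signature gene counts exceed n_genes")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be strictly positive")
        if self.litter_sd < 0:
            raise ValueError("litter_sd must be non-negative")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be positive and ordered")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("gene_length_range must be positive and ordered")
        if len(set(self.treatments)) != len(self.treatments) or not self.treatments:
            raise ValueError("treatments must be nonempty and unique")
        if len(set(self.timepoints)) != len(self.timepoints) or not self.timepoints:
            raise ValueError("timepoints must be nonempty and unique")


@dataclass
class SimOutput:
    """Simulated experiment plus per-gene ground truth."""

    counts: ExpressionMatrix
    tpm: ExpressionMatrix
    samples: SampleTable
    truth: pd.DataFrame  # signature, log2fc per timepoint, baseline, length
    gene_lengths: pd.Series
    signatures: list[GeneSignature]

    def write(self, outdir) -> None:
        from pathlib import Path
        from .io import write_signatures
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_tsv(outdir / "counts.tsv")
        self.tpm.to_tsv(outdir / "tpm.tsv")
        self.samples.to_tsv(outdir / "samples.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index_label="gene_id")
        if self.signatures:
            write_signatures(self.signatures, outdir / "signatures.gmt")


def counts_to_tpm(counts: ExpressionMatrix, gene_lengths: pd.Series
                  ) -> ExpressionMatrix:
    """Length-normalise counts to transcripts per million.

    TPM_gj = (count_gj / length_g) / sum_i (count_ij / length_i) * 1e6, so
    every non-degenerate column sums to 1e6. An all-zero sample cannot be
    normalised and yields an all-zero column with a warning.
    """
    lengths = gene_lengths.reindex(counts.values.index)
    if lengths.isna().any():
        missing = list(counts.values.index[lengths.isna()])[:5]
        raise ValueError(f"gene length missing for: {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be strictly positive")
    rate = counts.values.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        log.warning("sample(s) with zero total counts cannot be TPM-normalised: %s",
                    list(denom.index[zero]))
        denom = denom.mask(zero, 1.0)
    tpm = rate.div(denom, axis=1) * 1e6
    tpm.loc[:, zero] = 0.0
    return ExpressionMatrix(tpm, "TPM")


def simulate_experiment(config: SimConfig) -> SimOutput:
    """Draw one synthetic experiment; bit-reproducible for a given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    width = max(4, len(str(n)))
    gene_ids = np.array([f"g{i:0{width}d}" for i in range(1, n + 1)])

    base_ln = rng.uniform(*config.baseline_log_mean_range, size=n)
    weights = np.exp(base_ln)
    lo, hi = config.gene_length_range
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    perm = rng.permutation(n)
    ieg_idx = perm[:config.ieg_genes]
    mg_idx = perm[config.ieg_genes:config.ieg_genes + config.microglia_genes]

    litters = [f"L{i}" for i in range(1, config.n_litters + 1)]
    litter_eff = {l: rng.normal(0.0, config.litter_sd, size=n) for l in litters}

    rows, meta = [], []
    r = 1.0 / config.nb_dispersion  # NB size parameter
    total_w = weights.sum()
    for litter in litters:
        for treatment in config.treatments:
            for timepoint in config.timepoints:
                sid = f"{litter}_{treatment}_{timepoint}"
                delta = np.zeros(n)
                if treatment == "EE":
                    if timepoint == "1h":
                        delta[ieg_idx] += config.ieg_log2fc
                    delta[mg_idx] += config.microglia_log2fc
                lib = rng.uniform(*config.library_size_range)
                mu = lib * weights * np.exp(litter_eff[litter]) * 2.0 ** delta / total_w
                counts = rng.negative_binomial(r, r / (r + mu))
                rows.append(counts)
                meta.append((sid, litter, treatment, timepoint, "M"))

    sample_ids = [m[0] for m in meta]
    counts_df = pd.DataFrame(np.column_stack(rows), index=gene_ids,
                             columns=sample_ids)
    counts_mat = ExpressionMatrix(counts_df.astype(np.int64).astype(float), "counts")
    lengths_s = pd.Series(lengths, index=gene_ids, name="length")
    tpm = counts_to_tpm(counts_mat, lengths_s)

    samples = SampleTable(pd.DataFrame(
        [m[1:] for m in meta], index=pd.Index(sample_ids, name="sample_id"),
        columns=["litter", "treatment", "timepoint", "sex"]))

    signature = np.full(n, "none", dtype=object)
    signature[ieg_idx] = "ieg"
    signature[mg_idx] = "microglia"
    lfc_1h = np.zeros(n)
    lfc_1h[ieg_idx] = config.ieg_log2fc
    lfc_1h[mg_idx] = config.microglia_log2fc
    lfc_4h = np.zeros(n)
    lfc_4h[mg_idx] = config.microglia_log2fc
    truth = pd.DataFrame({
        "signature": signature,
        "log2fc_1h": lfc_1h,
        "log2fc_4h": lfc_4h,
        "baseline_ln_mean": base_ln,
        "length": lengths,
    }, index=gene_ids)

    signatures = []
    if config.ieg_genes:
        signatures.append(GeneSignature("IEG", frozenset(gene_ids[ieg_idx]), "up"))
    if config.microglia_genes:
        signatures.append(GeneSignature(
            "microglia", frozenset(gene_ids[mg_idx]), "down"))

    return SimOutput(counts_mat, tpm, samples, truth, lengths_s, signatures)
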