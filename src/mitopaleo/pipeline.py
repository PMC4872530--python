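"""End-to-end pipeline: simulate/ingest -> consensus -> damage ->
contamination -> haplogroup -> optional TMRCA, with a JSON run report.

Stages communicate only through declared file formats and in-memory
results; each stage can be toggled off.  The report records every
threshold and seed actually used, plus a hash of the configuration, so a
rerun with the same config and inputs reproduces it byte-for-byte (modulo
nothing: no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

from . import __version__, io
from .clock import ClockMCMCConfig, ClockPrior, mcmc_tmrca, rho_tmrca, simulate_clade
from .consensus import build_pileup, call_consensus, mean_coverage
from .contamination import (
    MixtureMCMCConfig,
    count_conflicting,
    find_private_sites,
    mixture_estimate,
    private_site_estimate,
)
from .damage import authenticate, damage_profile, fit_decay, profile_table
from .fixtures import (
    contaminant_haplotype,
    mixture_panel,
    packaged_archaic_sites,
    pm1_haplotype,
    worldwide_panel,
)
from .haplotyping import archaic_screen, classify_haplogroup, private_mutations
from .reference import load_reference
from .simulate import SimConfig, simulate_reads
from .variants import diff_vs_reference, format_variants


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run (key = stage.parameter)."""

    # inputs: either simulate reads or read an aligned SAM
    input_sam: str = ""  # empty -> simulate
    output_dir: str = "mitopaleo_out"

    simulate_depth: float = 33.0
    simulate_deamination_rate: float = 0.30
    simulate_deamination_decay: float = 0.60
    simulate_seq_error: float = 0.002
    simulate_contamination: float = 0.0
    simulate_seed: int = 1

    consensus_min_depth: int = 3
    consensus_min_support: float = 0.6

    damage_enabled: bool = True
    damage_positions: int = 15
    damage_min_terminal_rate: float = 0.05

    contamination_enabled: bool = True
    contamination_method: str = "both"  # private | mixture | both
    contamination_freq_threshold: float = 0.05
    contamination_mcmc_iter: int = 5000
    contamination_seed: int = 2

    haplotype_enabled: bool = True

    tmrca_enabled: bool = False
    tmrca_fasta: str = ""  # with tmrca_ages; empty -> simulate a clade
    tmrca_ages: str = ""
    tmrca_true: float = 50_000.0
    tmrca_n_tips: int = 20
    tmrca_rate_mean: float = 2.06e-8
    tmrca_rate_sd: float = 1.94e-9
    tmrca_mcmc_iter: int = 6000
    tmrca_seed: int = 3

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        values: dict[str, object] = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, _, raw = line.partition("=")
                key = key.strip()
                if key not in types:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                current = getattr(defaults, key)
                if isinstance(current, bool):
                    values[key] = raw.strip().lower() in ("1", "true", "yes")
                else:
                    values[key] = type(current)(raw.strip())
        return cls(**values)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run report (also written to ``output_dir/report.json``).
    A stage failure is recorded under ``errors`` and dependent stages are
    skipped; completed stages keep their outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference = load_reference()
    report: dict = {
        "version": __version__,
        "config_hash": config.digest(),
        "config": dataclasses.asdict(config),
        "errors": {},
    }

    # --- reads -----------------------------------------------------------
    source = pm1_haplotype()
    if config.input_sam:
        reads = io.read_sam(config.input_sam)
    else:
        contaminant = (
            contaminant_haplotype() if config.simulate_contamination > 0 else None
        )
        sim = SimConfig(
            target_mean_depth=config.simulate_depth,
            deamination_rate=config.simulate_deamination_rate,
            deamination_decay=config.simulate_deamination_decay,
            seq_error=config.simulate_seq_error,
            contamination_fraction=config.simulate_contamination,
            contaminant=contaminant,
            seed=config.simulate_seed,
        )
        reads = simulate_reads(source, sim)
        io.write_sam(reads, out / "reads.sam")
    report["n_reads"] = len(reads)

    # --- consensus -------------------------------------------------------
    pileup = build_pileup(reads)
    consensus = call_consensus(
        pileup,
        min_depth=config.consensus_min_depth,
        min_support=config.consensus_min_support,
    )
    io.write_fasta({"consensus": consensus.sequence}, out / "consensus.fasta")
    report["coverage"] = {
        "mean_depth": round(mean_coverage(pileup), 3),
        "n_uncalled_sites": consensus.sequence.count("N"),
        "min_depth": config.consensus_min_depth,
        "min_support": config.consensus_min_support,
    }

    # --- damage ----------------------------------------------------------
    if config.damage_enabled:
        try:
            profile = damage_profile(reads, consensus, config.damage_positions)
            verdict = authenticate(profile, config.damage_min_terminal_rate)
            fit = fit_decay(profile)
            profile_table(profile).to_csv(
                out / "damage_profile.tsv", sep="\t", index=False
            )
            report["damage"] = {
                "ancient_consistent": verdict.ancient_consistent,
                "terminal_ct_rate": round(verdict.terminal_ct_rate, 4),
                "terminal_ga_rate": round(verdict.terminal_ga_rate, 4),
                "delta0_hat": round(fit.delta0, 4),
                "lambda_hat": round(fit.lam, 4) if np.isfinite(fit.lam) else None,
                "min_terminal_rate": config.damage_min_terminal_rate,
                "rationale": verdict.rationale,
            }
        except Exception as exc:  # pragma: no cover - defensive
            report["errors"]["damage"] = str(exc)

    # --- contamination ---------------------------------------------------
    if config.contamination_enabled:
        try:
            section: dict = {}
            if config.contamination_method in ("private", "both"):
                panel = worldwide_panel()
                sites = find_private_sites(
                    consensus, panel, config.contamination_freq_threshold
                )
                k, n = count_conflicting(reads, sites)
                est = private_site_estimate(k, n)
                section["private_site"] = {
                    "n_private_sites": len(sites),
                    "n_conflicting": k,
                    "n_total": n,
                    "c_hat": round(est.c_hat, 4),
                    "ci_low": round(est.ci_low, 4),
                    "ci_high": round(est.ci_high, 4),
                }
            if config.contamination_method in ("mixture", "both"):
                panel = mixture_panel()
                est = mixture_estimate(
                    reads,
                    consensus,
                    panel,
                    MixtureMCMCConfig(
                        n_iter=config.contamination_mcmc_iter,
                        seed=config.contamination_seed,
                    ),
                )
                io.write_trace(est.trace, ["c", "eps"], out / "mixture_trace.tsv")
                section["mixture"] = {
                    "c_hat": round(est.c_hat, 4),
                    "ci_low": round(est.ci_low, 4),
                    "ci_high": round(est.ci_high, 4),
                    "eps_hat": round(est.eps_hat, 5),
                    "ess": round(est.ess, 1),
                    "converged": est.converged,
                    "seed": config.contamination_seed,
                }
            report["contamination"] = section
        except Exception as exc:
            report["errors"]["contamination"] = str(exc)

    # --- haplotype -------------------------------------------------------
    if config.haplotype_enabled:
        try:
            variants, n_sites = diff_vs_reference(consensus.sequence, reference)
            io.write_variants_tsv(variants, out / "variants.tsv")
            call = classify_haplogroup(variants)
            screen = archaic_screen(variants, packaged_archaic_sites())
            private = private_mutations(variants, worldwide_panel())
            report["haplotype"] = {
                "n_variants": len(variants),
                "variants": format_variants(variants),
                "n_uncalled_sites": len(n_sites),
                "haplogroup": call.display_name,
                "basal": call.basal,
                "matched_diagnostics": {
                    k: format_variants(v) for k, v in call.matched.items()
                },
                "archaic_sites_screened": screen.n_sites,
                "archaic_matches": screen.n_matching,
                "private_mutations": format_variants(private),
            }
        except Exception as exc:
            report["errors"]["haplotype"] = str(exc)

    # --- tmrca -----------------------------------------------------------
    if config.tmrca_enabled:
        try:
            prior = ClockPrior(config.tmrca_rate_mean, config.tmrca_rate_sd)
            if config.tmrca_fasta:
                tips = io.read_tip_dated(config.tmrca_fasta, config.tmrca_ages)
            else:
                ages = [0.0] * (config.tmrca_n_tips - 1) + [35_000.0]
                tips = simulate_clade(
                    config.tmrca_true,
                    ages,
                    prior.rate_mean,
                    reference,
                    seed=config.tmrca_seed,
                )
            rho = rho_tmrca(tips, reference, prior.rate_mean)
            mcmc = mcmc_tmrca(
                tips,
                prior,
                ClockMCMCConfig(
                    n_iter=config.tmrca_mcmc_iter, seed=config.tmrca_seed
                ),
            )
            io.write_trace(mcmc.trace, ["root_age", "rate"], out / "tmrca_trace.tsv")
            report["tmrca"] = {
                "rho_point_ky": round(rho.point / 1000, 2),
                "mcmc_point_ky": round(mcmc.point / 1000, 2),
                "hpd_low_ky": round(mcmc.hpd_low / 1000, 2),
                "hpd_high_ky": round(mcmc.hpd_high / 1000, 2),
                "ess": round(mcmc.ess, 1),
                "converged": mcmc.converged,
                "seed": config.tmrca_seed,
            }
        except Exception as exc:
            report["errors"]["tmrca"] = str(exc)

    io.write_report(report, out / "report.json")
    return report
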