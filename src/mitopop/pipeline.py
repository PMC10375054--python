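"""End-to-end analysis: alignment -> haplotypes, diversity, structure,
demography and network reports.

``run_full_analysis`` reproduces the standard single-locus workflow for an
aligned mtDNA dataset: haplotype count table, per-population diversity,
AMOVA, pairwise Phi_ST / d_xy, neutrality tests with mismatch-distribution
fits and expansion dating, a median-joining network and a bootstrapped NJ
tree.  All stochastic stages draw their seeds deterministically from one
top-level seed, so a re-run with an identical configuration is
byte-identical.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._seeds import derive_seed
from .alignment import (
    SequenceAlignment,
    base_composition,
    best_frame,
    check_orf,
    classify_sites,
    read_fasta,
    write_site_report,
)
from .demography import (
    expansion_time,
    fit_sudden_expansion,
    gof_bootstrap,
    mismatch_observed,
    neutrality_tests,
)
from .diversity import summarize_diversity
from .haplotypes import collapse_haplotypes, dominant_haplotype, sharing_profile
from .network import median_joining
from .structure import (
    amova,
    bootstrap_support,
    nj_tree,
    pairwise_difference_matrix,
    pairwise_structure,
)


@dataclass
class AnalysisConfig:
    """Inputs, replicate counts and seeds for one full run."""

    fasta: Path | str | None = None
    popmap: Path | str | None = None
    outdir: Path | str = "mitopop_out"
    n_permutations: int = 10000
    n_bootstrap: int = 1000  # NJ bootstrap replicates
    n_coalescent: int = 1000  # neutrality-test null replicates
    n_mismatch_bootstrap: int = 1000  # SSD/raggedness parametric bootstrap
    rate: str = "3.1%/Myr"
    generation_years: float = 1.0
    epsilon: float = 0.0  # median-joining tolerance
    nj_on_haplotypes: bool = True
    mismatch_scope: str = "per_population"  # or "pooled" or "both"
    orf_frame: "int | str" = "auto"
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)


def run_full_analysis(
    config: AnalysisConfig, aln: SequenceAlignment | None = None
) -> dict[str, Path]:
    """Run every stage and write the report bundle to ``config.outdir``.

    Returns a mapping from report name to file path.
    """
    if aln is None:
        if config.fasta is None or config.popmap is None:
            raise ValueError("either an alignment or fasta+popmap paths are required")
        aln = read_fasta(config.fasta, config.popmap)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    log_lines: list[str] = [
        f"mitopop {__version__}",
        f"python {sys.version.split()[0]}",
        f"n_sequences {aln.n_sequences}",
        f"alignment_length {aln.length}",
        f"populations {','.join(aln.population_labels)}",
    ]
    log_lines += [f"config.{k} {v}" for k, v in asdict(config).items()]

    # -- alignment summaries ---------------------------------------------
    comp = base_composition(aln)
    log_lines.append(
        "base_composition "
        + " ".join(f"{b}={comp[b]:.4f}" for b in ("A", "T", "C", "G"))
    )
    sc = classify_sites(aln)
    paths["sites"] = out / "sites.tsv"
    write_site_report(sc, paths["sites"])
    log_lines.append(
        f"variable_sites {sc.n_variable} "
        f"(parsimony_informative {sc.n_parsimony_informative}, "
        f"singleton {sc.n_singleton})"
    )
    frame = (
        best_frame(aln) if config.orf_frame == "auto" else int(config.orf_frame)
    )
    stops = check_orf(aln, frame=frame)
    n_flagged = sum(1 for v in stops.values() if v)
    log_lines.append(f"orf_frame {frame} sequences_with_premature_stops {n_flagged}")

    # -- haplotypes and diversity ----------------------------------------
    table = collapse_haplotypes(aln)
    paths["table1"] = out / "table1.tsv"
    table.write_tsv(paths["table1"])
    paths["haplotypes_fasta"] = out / "haplotypes.fasta"
    table.write_fasta(paths["haplotypes_fasta"])
    share = sharing_profile(table)
    dom = dominant_haplotype(table)
    log_lines.append(
        f"haplotypes {table.k} private {share.n_private} shared {share.n_shared} "
        f"dominant {dom.name} ({dom.frequency_pct:.2f}% in {dom.n_populations} populations)"
    )
    div = summarize_diversity(table, aln)
    paths["table2"] = out / "table2.tsv"
    div_out = div.copy()
    div_out["h"] = div_out["h"].round(3)
    div_out["pi"] = div_out["pi"].round(5)
    div_out.to_csv(paths["table2"], sep="\t")

    # -- structure ---------------------------------------------------------
    dist = pairwise_difference_matrix(aln)
    amova_res = amova(
        dist,
        aln.populations,
        n_perm=config.n_permutations,
        seed=config.stage_seed("amova"),
    )
    paths["table3"] = out / "table3.tsv"
    amova_res.to_frame().to_csv(paths["table3"], sep="\t", index=False)
    pw = pairwise_structure(
        aln, n_perm=config.n_permutations, seed=config.stage_seed("pairwise_phist")
    )
    paths["table4"] = out / "table4.tsv"
    pw.combined_table().to_csv(paths["table4"], sep="\t")
    pw.p_values.to_csv(out / "table4_pvalues.tsv", sep="\t")
    pw.p_values_holm.to_csv(out / "table4_pvalues_holm.tsv", sep="\t")

    # -- demography --------------------------------------------------------
    neut = neutrality_tests(
        aln, n_sims=config.n_coalescent, seed=config.stage_seed("neutrality")
    )
    scopes = list(aln.population_labels)
    if config.mismatch_scope in ("pooled", "both"):
        scopes.append("all")
    if config.mismatch_scope == "pooled":
        scopes = ["all"]
    mm_rows = []
    for pop in scopes:
        sub = aln.subset(pop)
        obs = mismatch_observed(sub)
        fit = fit_sudden_expansion(obs)
        p_ssd, p_rag = gof_bootstrap(
            fit,
            sub.n_sequences,
            n_boot=config.n_mismatch_bootstrap,
            seed=derive_seed(config.seed, f"mismatch:{pop}"),
        )
        est = expansion_time(
            fit.tau, config.rate, aln.length, config.generation_years
        )
        mm_rows.append(
            dict(
                population=pop,
                tau=fit.tau,
                theta0=fit.theta0,
                theta1=fit.theta1,
                SSD=fit.ssd,
                SSD_pvalue=p_ssd,
                raggedness=fit.raggedness,
                raggedness_pvalue=p_rag,
                t_years=est.t_years,
            )
        )
        hist = pd.DataFrame(
            {
                "differences": np.arange(len(obs)),
                "observed": obs,
                "expected": fit.expected,
            }
        )
        hist.to_csv(out / f"mismatch_{pop}.tsv", sep="\t", index=False)
    mm = pd.DataFrame(mm_rows).set_index("population")
    table5 = neut.join(mm, how="outer")
    paths["table5"] = out / "table5.tsv"
    table5.to_csv(paths["table5"], sep="\t")

    # -- network and tree ---------------------------------------------------
    net = median_joining(table, epsilon=config.epsilon)
    paths["network_nodes"] = out / "network_nodes.tsv"
    paths["network_edges"] = out / "network_edges.tsv"
    net.write_tsv(paths["network_nodes"], paths["network_edges"])

    if config.nj_on_haplotypes:
        tree_aln = SequenceAlignment(
            ids=table.names,
            populations=tuple("hap" for _ in table.names),
            sequences=table.sequences,
        )
    else:
        tree_aln = aln
    if tree_aln.n_sequences >= 3:
        tree, support = bootstrap_support(
            tree_aln, n_reps=config.n_bootstrap, seed=config.stage_seed("nj_bootstrap")
        )
        newick = tree.newick(support=support)
    else:
        newick = tree_aln.ids[0] + ";" if tree_aln.n_sequences == 1 else None
        if newick is None:
            tree = nj_tree(pairwise_difference_matrix(tree_aln))
            newick = tree.newick()
    paths["tree"] = out / "tree.nwk"
    paths["tree"].write_text(newick + "\n")

    paths["log"] = out / "run_log.txt"
    paths["log"].write_text("\n".join(log_lines) + "\n")
    return paths
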