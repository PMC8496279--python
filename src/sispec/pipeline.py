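"""End-to-end pipeline: extract -> intersect -> filter -> bin -> analyze.

Runs the full per-bin analysis for one focal species (the species whose
polymorphism sample is provided): SI extraction in both species, homologous
intersection through WGA columns, site filtering, GC binning, est-sfs-style
polarization, class-SFS model fitting (gamma, kappa, LRTs), diversity and
DAF summaries, and lineage-specific substitution counting, writing
per-bin tables, figures and a machine-readable JSON summary.  All
randomness flows from one master seed, split per stage and per bin, so the
summary is byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import binning as bng
from . import divergence as dvg
from . import polarization as pol
from . import popgen as pg
from . import sfs_model as sm
from .sfs import CLASSES, ClassSFS

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    gff_a: str
    fasta_a: str
    gff_b: str
    fasta_b: str
    wga: str
    haplotypes_a: str
    outdir: str
    species_a: str = "A"
    species_b: str = "B"
    exclude_beds: dict = field(default_factory=dict)  # species -> [bed paths]
    qual_threshold: float = 30.0
    strategy: str = "species"  # binning basis for the polymorphism analyses
    k_bins: int = 5
    n_boot: int = 200
    seed: int = 0
    polarize_restarts: int = 10
    fit_models: tuple = ("M0", "M1")
    fit_restarts: int = 5
    divergence_runs: int = 10
    drop_polymorphic: bool = False
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fit_models" in data:
            data["fit_models"] = tuple(data["fit_models"])
        return cls(**data)

    def validate(self) -> None:
        for key in ("gff_a", "fasta_a", "gff_b", "fasta_b", "wga", "haplotypes_a"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p}")
        if self.k_bins <= 0:
            raise ValueError("k_bins must be positive")
        if self.strategy not in ("mean", "species"):
            raise ValueError("strategy must be 'mean' or 'species'")


def _paired_introns(si_a, si_b, sites, species_a, species_b):
    """Merge the single-species intron records of homologous pairs."""
    by_id_a = {r.intron_id: r for r in si_a}
    by_id_b = {r.intron_id: r for r in si_b}
    pairs = {}
    for s in sites:
        key = (s.intron_id, s.intron_id_b)
        if key in pairs or s.intron_id_b not in by_id_b:
            continue
        a, b = by_id_a[s.intron_id], by_id_b[s.intron_id_b]
        rec = ann.IntronRecord(
            intron_id=a.intron_id,
            chrom={**a.chrom, **b.chrom},
            start={**a.start, **b.start},
            end={**a.end, **b.end},
            strand={**a.strand, **b.strand},
            sequence={**a.sequence, **b.sequence},
            si_start={**a.si_start, **b.si_start},
            si_end={**a.si_end, **b.si_end},
            gc_species={**a.gc_species, **b.gc_species},
        )
        pairs[key] = rec
    return list(pairs.values())


def _daf_from_sites(site_rows, n):
    sfs = pol.build_class_sfs(site_rows, n)
    return pg.mean_daf(sfs).daf, sfs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and writes) the summary dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True, default=str)
    )
    seeds = np.random.SeedSequence(config.seed).spawn(4 + config.k_bins)
    sa, sb = config.species_a, config.species_b

    stage = "extract"
    try:
        si_a = ann.extract_short_introns(config.gff_a, config.fasta_a, sa)
        si_b = ann.extract_short_introns(config.gff_b, config.fasta_b, sb)
        stage = "intersect"
        sites = ann.intersect_homologous_sites(si_a, si_b, config.wga, sa, sb)
        stage = "attach_polymorphism"
        sites = ann.attach_polymorphism(sites, config.haplotypes_a, sa)
        stage = "filter"
        exclusions = {
            sp: _merged_trees(paths) for sp, paths in config.exclude_beds.items()
        }
        div_sites = ann.apply_site_filters(
            sites, exclusions, config.qual_threshold, polymorphism_mode=False
        )
        poly_sites = ann.apply_site_filters(
            div_sites, None, config.qual_threshold, polymorphism_mode=True
        )
        stage = "bin"
        introns = _paired_introns(si_a, si_b, div_sites, sa, sb)
        strategy = sa if config.strategy == "species" else "mean"
        bins = bng.assign_bins(introns, strategy=strategy, k=config.k_bins)
        id_to_bin = {
            iid: b.bin_index for b in bins for iid in b.intron_ids
        }
        stage = "analyze"
        n = len(poly_sites[0].ingroup_column) if poly_sites else 0
        bin_results = []
        for b in bins:
            bin_results.append(
                _analyze_bin(
                    b,
                    [s for s in poly_sites if id_to_bin.get(s.intron_id) == b.bin_index],
                    [s for s in div_sites if id_to_bin.get(s.intron_id) == b.bin_index],
                    n,
                    config,
                    seeds[3 + b.bin_index],
                )
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    summary = {
        "species_a": sa,
        "species_b": sb,
        "strategy": config.strategy,
        "seed": config.seed,
        "n_introns": len(introns),
        "n_sites_divergence": len(div_sites),
        "n_sites_polymorphism": len(poly_sites),
        "bins": bin_results,
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float)
    )
    _write_tables(summary, outdir)
    if config.make_plots:
        _write_plots(summary, outdir)
    return summary


def _merged_trees(paths):
    from intervaltree import IntervalTree

    merged: dict[str, IntervalTree] = {}
    for p in paths:
        for chrom, tree in ann.read_bed(p).items():
            dst = merged.setdefault(chrom, IntervalTree())
            for iv in tree:
                dst.addi(iv.begin, iv.end)
    return merged


def _analyze_bin(b, poly_sites, div_sites, n, config, seed_seq):
    rng = np.random.default_rng(seed_seq)
    result = {
        "bin_index": b.bin_index,
        "strategy": b.strategy,
        "gc_range": [float(x) for x in b.gc_range],
        "n_introns": len(b.intron_ids),
        "n_sites_polymorphism": len(poly_sites),
        "n_sites_divergence": len(div_sites),
    }

    # ---- polymorphism side ----
    if poly_sites:
        model = pol.fit_outgroup_model(
            poly_sites, n_restarts=config.polarize_restarts,
            seed=int(rng.integers(2**31)),
        )
        polarized = pol.polarize(poly_sites, model)
        sfs = pol.build_class_sfs(polarized, n)
        counts = np.array([s.n_minor for s in polarized])
        div = pg.diversity_summary(counts, n, sfs=sfs)
        result["diversity"] = {
            "pi": div.pi,
            "theta_w": div.theta_w,
            "tajima_d": div.tajima_d,
            "prop_singletons": div.prop_singletons,
            "singleton_ratio": div.singleton_ratio,
        }
        result["daf"] = pg.mean_daf(sfs).daf
        fits = {}
        for mdl in config.fit_models:
            f = sm.fit_model(
                sfs, mdl, n_restarts=config.fit_restarts,
                seed=int(rng.integers(2**31)),
            )
            fits[mdl] = f
            result[f"fit_{mdl}"] = {
                "gamma": f.gamma,
                "kappa": f.kappa,
                "loglik": f.loglik,
                "epsilon": f.epsilon,
            }
        if "M0" in fits and "M1" in fits:
            stat, df, p = sm.likelihood_ratio_test(fits["M0"], fits["M1"])
            result["lrt_M0_M1"] = {"stat": stat, "df": df, "p": p}

    # ---- divergence side ----
    if div_sites:
        use = div_sites
        if config.drop_polymorphic:
            use = [
                s
                for s in div_sites
                if not s.ingroup_column or len(set(s.ingroup_column) - {"N"}) <= 1
            ]
        c64 = dvg.pattern_counts(
            "".join(s.ref_allele[config.species_a] for s in use),
            "".join(s.ref_allele[config.species_b] for s in use),
            "".join(s.outgroup_allele for s in use),
        )
        model = dvg.fit_nonstationary(
            c64, n_runs=config.divergence_runs, seed=int(rng.integers(2**31))
        )
        counts = dvg.expected_substitution_counts(c64, model)
        stat, df, p = dvg.nonstationarity_test(model)
        result["nonstationarity_lrt"] = {"stat": stat, "df": df, "p": p}
        for lin, key in (("in1", config.species_a), ("in2", config.species_b)):
            sc = counts[lin]
            chi_stat, chi_p = dvg.equilibrium_chi2(sc.n_ws, sc.n_sw)
            result[f"divergence_{key}"] = {
                "n_sw": sc.n_sw,
                "n_ws": sc.n_ws,
                "n_neu": sc.n_neu,
                "L_GC": sc.L_GC,
                "L_AT": sc.L_AT,
                "r_sw": sc.r_sw,
                "r_ws": sc.r_ws,
                "R": sc.R,
                "ancestral_gc": sc.ancestral_gc,
                "count_ratio_ws_sw": sc.n_ws / sc.n_sw if sc.n_sw else np.nan,
                "equilibrium_chi2": chi_stat,
                "equilibrium_p": chi_p,
            }
    return result


def _write_tables(summary, outdir: Path) -> None:
    rows = []
    for b in summary["bins"]:
        row = {
            "bin": b["bin_index"],
            "strategy": b["strategy"],
            "population": summary["species_a"],
            "gc_low": b["gc_range"][0],
            "gc_high": b["gc_range"][1],
            "n_introns": b["n_introns"],
        }
        for key in ("diversity", "daf"):
            for k, v in b.get(key, {}).items():
                row[f"{key}_{k}"] = v
        for key, val in b.items():
            if key.startswith(("fit_", "divergence_", "lrt_")):
                if isinstance(val, dict):
                    for k, v in val.items():
                        row[f"{key}_{k}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "per_bin.tsv", sep="\t", index=False)


def _write_plots(summary, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = summary["bins"]
    x = [b["bin_index"] for b in bins]
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    sa = summary["species_a"]

    if all("divergence_" + sa in b for b in bins):
        axes[0].plot(x, [b["divergence_" + sa]["count_ratio_ws_sw"] for b in bins], "o-")
        axes[0].axhline(1.0, ls="--", c="grey")
        axes[0].set_ylabel(r"$N_{W>S}/N_{S>W}$")
        axes[2].plot(x, [b["divergence_" + sa]["R"] for b in bins], "o-")
        axes[2].set_ylabel(r"$R = r_{S>W}/r_{W>S}$")
    if all("daf" in b for b in bins):
        for cls, marker in zip(CLASSES, "ov^"):
            axes[1].plot(x, [b["daf"][cls] for b in bins], marker + "-", label=cls)
        axes[1].legend()
        axes[1].set_ylabel("mean DAF")
    for ax in axes:
        ax.set_xlabel("GC bin")
    fig.tight_layout()
    fig.savefig(outdir / "per_bin.png", dpi=120)
    plt.close(fig)

    if all("fit_M1" in b for b in bins):
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        axes[0].plot(x, [b["fit_M1"]["gamma"] for b in bins], "o-")
        axes[0].axhline(0.0, ls="--", c="grey")
        axes[0].set_ylabel(r"$\hat\gamma$")
        axes[1].plot(x, [b["fit_M1"]["kappa"] for b in bins], "o-")
        axes[1].set_ylabel(r"$\hat\kappa$")
        for ax in axes:
            ax.set_xlabel("GC bin")
        fig.tight_layout()
        fig.savefig(outdir / "gamma_kappa.png", dpi=120)
        plt.close(fig)
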