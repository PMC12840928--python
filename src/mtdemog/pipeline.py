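"""End-to-end orchestration: QC -> diversity -> neutrality -> mismatch ->
(with outgroups) polarization/SFS/rate/TMRCA -> report tables.

A run is described by a :class:`RunConfig` (flat key=value config file with
CLI overrides; precedence CLI > file > defaults).  Every stochastic stage
derives its own seed from the master seed, all seeds and replicate counts are
logged, and identical configs reproduce byte-identical JSON reports.  Stage
failures are recorded with stage-named diagnostics and do not discard the
outputs of earlier stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import ancestral as anc_mod
from . import diversity as div_mod
from . import mismatch as mm_mod
from . import neutrality as neut_mod
from . import ratecal as rate_mod
from . import tmrca as tmrca_mod
from .alignment import Alignment, classify_sites, collapse_haplotypes, qc_coding, read_fasta, trim_window

logger = logging.getLogger("mtdemog")

#: default rate and calibration settings: ~1% per Ma substitution rate,
#: fossil split at 4.6 Ma (midpoint of a 4-5.2 Ma interval), generation time
#: 9.2 years
DEFAULTS = {
    "rate_per_site_year": 1e-8,
    "calibration_T_years": 4.6e6,
    "calibration_T_lo": 4.0e6,
    "calibration_T_hi": 5.2e6,
    "generation_time": 9.2,
    "distance_model": "TN93",
    "neutrality_reps": 10_000,
    "mismatch_B": 1000,
    "dxy_B": 1000,
    "thomson_B": 1000,
    "seed": 0,
}


@dataclass
class RunConfig:
    fasta: str
    metadata: str | None = None
    outgroup_fasta: str | None = None
    window_start: int | None = None
    window_end: int | None = None
    distance_model: str = DEFAULTS["distance_model"]
    rate_per_site_year: float = DEFAULTS["rate_per_site_year"]
    calibrate_rate: bool = True  # re-derive the rate from d_xy when outgroups exist
    calibration_T_years: float = DEFAULTS["calibration_T_years"]
    calibration_T_lo: float = DEFAULTS["calibration_T_lo"]
    calibration_T_hi: float = DEFAULTS["calibration_T_hi"]
    generation_time: float = DEFAULTS["generation_time"]
    neutrality_reps: int = DEFAULTS["neutrality_reps"]
    mismatch_B: int = DEFAULTS["mismatch_B"]
    dxy_B: int = DEFAULTS["dxy_B"]
    thomson_B: int = DEFAULTS["thomson_B"]
    seed: int = DEFAULTS["seed"]
    outdir: str = "mtdemog_run"

    def stage_seed(self, stage_index: int) -> int:
        # deterministic per-stage seeds below 2^31
        return (self.seed * 1_000_003 + 7919 * stage_index + 1) % (2 ** 31)

    def to_flat(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is not None:
                lines.append(f"{f.name}={v}")
        return "\n".join(lines) + "\n"


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Parse a flat key=value config file; keyword overrides win."""
    values: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, raw = line.partition("=")
        values[key.strip()] = raw.strip()
    values.update({k: v for k, v in overrides.items() if v is not None})
    kwargs = {}
    for f in dataclasses.fields(RunConfig):
        if f.name not in values:
            continue
        raw = values[f.name]
        if isinstance(raw, str):
            if f.type in ("int", "int | None"):
                raw = int(raw)
            elif f.type in ("float",):
                raw = float(raw)
            elif f.type == "bool":
                raw = raw.lower() in ("1", "true", "yes")
        kwargs[f.name] = raw
    return RunConfig(**kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every applicable stage; return the report bundle as a dict.

    Writes ``report.json``, ``diversity_table.tsv``, ``dating_table.tsv``,
    the resolved config and a run log into ``config.outdir``.  Dating stages
    are skipped with a logged notice when no outgroups are configured.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    results: dict = {"config": dataclasses.asdict(config), "errors": {}}
    try:
        _run_stages(config, results)
    finally:
        logger.removeHandler(handler)
        handler.close()
    (outdir / "report.json").write_text(json.dumps(results, indent=2, default=str))
    (outdir / "config.txt").write_text(config.to_flat())
    report_tables(results, outdir)
    return results


def _run_stages(config: RunConfig, results: dict) -> None:
    aln = read_fasta(config.fasta, config.metadata)
    if config.window_start and config.window_end:
        aln = trim_window(aln, config.window_start, config.window_end)
        logger.info("trimmed to window %s..%s (L=%d)",
                    config.window_start, config.window_end, aln.length)
    outgroups = None
    if config.outgroup_fasta:
        outgroups = read_fasta(config.outgroup_fasta)

    def stage(name, fn):
        try:
            results[name] = fn()
            logger.info("stage %s: ok", name)
        except Exception as err:  # keep partial outputs, record diagnostics
            results["errors"][name] = f"{type(err).__name__}: {err}"
            logger.error("stage %s failed: %s", name, err)

    stage("qc", lambda: _stage_qc(aln))
    stage("haplotypes", lambda: _stage_haplotypes(aln))
    stage("diversity", lambda: div_mod.diversity_summary(aln).to_dict())
    stage("neutrality", lambda: _stage_neutrality(aln, config))
    stage("mismatch", lambda: _stage_mismatch(aln, config))
    if outgroups is None:
        logger.info("no outgroups configured: dating stages skipped")
        results["dating_skipped"] = True
        return
    stage("dating", lambda: _stage_dating(aln, outgroups, config))


def _stage_qc(aln: Alignment) -> dict:
    rep = qc_coding(aln)
    return {"passed": rep.passed, "gap_positions": rep.gap_positions,
            "internal_stops": rep.internal_stops,
            "n": aln.n, "L": aln.length}


def _stage_haplotypes(aln: Alignment) -> dict:
    table = collapse_haplotypes(aln)
    sites = classify_sites(aln)
    return {
        "n_haplotypes": table.n_haplotypes,
        "haplotypes": [{"label": h[0], "count": h[2], "members": list(h[3])}
                       for h in table.haplotypes],
        "S": sites.S,
        "singletons": sites.n_singletons,
        "parsimony_informative": sites.n_parsimony_informative,
        "segregating_positions": list(sites.segregating_positions),
    }


def _stage_neutrality(aln: Alignment, config: RunConfig) -> dict:
    out = {}
    for k, stat in enumerate(("D", "D*", "F*", "FS", "R2")):
        res = neut_mod.coalescent_pvalue(
            stat, aln, reps=config.neutrality_reps,
            seed=config.stage_seed(10 + k))
        out[stat] = {"value": res.value, "p": res.p_value,
                     "applicable": res.applicable,
                     "null_settings": res.null_settings}
    return out


def _stage_mismatch(aln: Alignment, config: RunConfig) -> dict:
    obs = div_mod.mismatch_observed(aln)
    fit = mm_mod.fit_sudden_expansion(obs, B=config.mismatch_B,
                                      seed=config.stage_seed(20))
    years, ci_years = mm_mod.tau_to_years(
        fit.tau, aln.length, config.rate_per_site_year, ci=fit.tau_ci)
    expected = mm_mod.expected_mismatch(fit.tau, fit.theta0,
                                        len(obs.counts) - 1)
    return {"observed_counts": list(obs.counts),
            "observed_freq": list(obs.frequencies),
            "expected_freq": [float(x) for x in expected],
            "tau": fit.tau, "theta0": fit.theta0, "ssd": fit.ssd,
            "p_ssd": fit.p_ssd, "raggedness": fit.raggedness,
            "p_raggedness": fit.p_raggedness, "tau_ci": fit.tau_ci,
            "converged": fit.converged,
            "expansion_time_years": years,
            "expansion_time_ci_years": ci_years,
            "B": fit.bootstrap_replicates}


def _stage_dating(aln: Alignment, outgroups: Alignment,
                  config: RunConfig) -> dict:
    out: dict = {}
    # substitution-rate calibration against the first (sister) outgroup
    sister = Alignment((outgroups.records[0],))
    dxy = rate_mod.dxy_between_groups(aln, sister,
                                      model=config.distance_model,
                                      B=config.dxy_B,
                                      seed=config.stage_seed(30))
    rate_est = rate_mod.rate_from_divergence(
        dxy, config.calibration_T_years,
        (config.calibration_T_lo, config.calibration_T_hi))
    out["dxy"] = {"d_xy": dxy.d_xy, "se": dxy.se, "model": dxy.model,
                  "B": dxy.bootstrap_replicates, "saturated": dxy.saturated}
    out["rate"] = {"mu_per_site_year": rate_est.mu,
                   "pct_per_ma": rate_est.pct_per_ma,
                   "ci_fixed_T_pct": rate_est.ci_fixed_T_pct(),
                   "ci_full_pct": rate_est.ci_full_pct(),
                   "T_years": rate_est.T_years,
                   "T_interval": rate_est.T_interval}
    rate = rate_est.mu if config.calibrate_rate else config.rate_per_site_year
    out["rate_used_per_site_year"] = rate

    # relative rate test: first two ingroup haplotypes vs sister, deeper outgroup
    if outgroups.n >= 2:
        m1, m2, stat, p = rate_mod.tajima_relative_rate(
            aln.records[0].sequence, outgroups.records[0].sequence,
            outgroups.records[1].sequence)
        out["relative_rate"] = {"m1": m1, "m2": m2, "chi2": stat, "p": p}

    # polarization and SFS under infinite sites
    filtered, removed, merges = anc_mod.infinite_sites_filter(aln)
    anc = anc_mod.estimate_ancestral(
        filtered, _project_outgroups(outgroups, aln.length, removed))
    sfs = anc_mod.unfolded_sfs(filtered, anc, removed_sites=tuple(removed))
    out["infinite_sites"] = {"removed_sites": removed, **merges}
    out["sfs"] = {"xi": list(sfs.counts), "n": sfs.n, "S": sfs.S}

    thomson = tmrca_mod.thomson_tmrca(sfs, rate, filtered.length,
                                      B=config.thomson_B,
                                      seed=config.stage_seed(40))
    out["tmrca_thomson"] = _tmrca_dict(thomson)

    # theta-based effective size and coalescent-unit conversion provenance
    sites = classify_sites(aln)
    theta_frag, _ = div_mod.watterson_theta(sites.S, aln.n, aln.length)
    n_ef = tmrca_mod.ne_from_theta(theta_frag, rate,
                                   config.generation_time, L=aln.length)
    out["theta_watterson_fragment"] = theta_frag
    out["N_ef_from_theta"] = n_ef
    return out


def _project_outgroups(outgroups: Alignment, L: int,
                       removed: list[int]) -> Alignment:
    from .ancestral import _remove_positions
    if outgroups.length != L:
        raise ValueError("outgroups must share ingroup coordinates")
    return _remove_positions(outgroups, removed)


def _tmrca_dict(est: tmrca_mod.TmrcaEstimate) -> dict:
    return {"method": est.method, "point_years": est.point_years,
            "dispersion_years": est.dispersion,
            "ci_years": list(est.ci_years), "assumptions": est.assumptions}


# ---------------------------------------------------------------------------
# Report tables


def report_tables(results: dict, outdir: str | Path) -> dict[str, Path]:
    """Write diversity (Table-1-shaped) and dating (Table-2-shaped) TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    div = results.get("diversity")
    neut = results.get("neutrality", {})
    if div:
        def fmt_stat(key):
            st = neut.get(key)
            if st is None or not st.get("applicable", False):
                return "NA"
            p = st.get("p")
            return f"{st['value']:.3f}" + (f" (p={p:.3f})" if p is not None else "")

        path = outdir / "diversity_table.tsv"
        with open(path, "w") as fh:
            fh.write("n\tS\tn_H\th\tpi\tD\tFS\tR2\n")
            fh.write("\t".join([
                str(div["n"]), str(div["S"]), str(div["n_H"]),
                f"{div['h']:.3f} ± {div['h_sd']:.3f}",
                f"{div['pi']:.4f} ± {div['pi_sd']:.4f}",
                fmt_stat("D"), fmt_stat("FS"), fmt_stat("R2"),
            ]) + "\n")
        paths["diversity"] = path

    mm = results.get("mismatch")
    if mm and "observed_freq" in mm:
        path = outdir / "mismatch_table.tsv"
        with open(path, "w") as fh:
            fh.write("i\tobserved\texpected\n")
            for i, (o, e) in enumerate(zip(mm["observed_freq"],
                                           mm["expected_freq"])):
                fh.write(f"{i}\t{o:.6f}\t{e:.6f}\n")
        paths["mismatch"] = path

    dating = results.get("dating")
    if dating:
        path = outdir / "dating_table.tsv"
        with open(path, "w") as fh:
            fh.write("method\tpoint_years\tci_low\tci_high\tassumptions\n")
            th = dating.get("tmrca_thomson")
            if th:
                fh.write("\t".join([
                    "thomson", f"{th['point_years']:.0f}",
                    f"{th['ci_years'][0]:.0f}", f"{th['ci_years'][1]:.0f}",
                    json.dumps(th["assumptions"], default=str),
                ]) + "\n")
        paths["dating"] = path
    return paths
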