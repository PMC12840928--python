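"""Coalescent simulator with infinite-sites mutations and calibrated outgroups.

Generates the synthetic inputs the analysis modules expect: haploid Kingman
genealogies under constant size or exponential growth, infinite-sites
mutations dropped on branches, and one or two outgroup sequences evolved under
a Jukes-Cantor process at deep, fossil-calibrated divergences.  Every dataset
carries full ground truth (genealogy, TMRCA, true SFS, true ancestral
sequence, mutated positions) so estimator tests can compare against the
generating process rather than against another estimator.

Units: genealogy time is measured in coalescent units of N_ef generations;
theta = 2 N_ef u per fragment per generation, so a branch of length t carries
Poisson(theta/2 * t) mutations.  Conversion to years happens only at the
calibration layer (substitution rate per site per year and generation time).

Exponential growth uses the standard deterministic time rescaling of the
constant-size coalescent: looking backwards, relative size nu(t) = exp(-rho t)
with rho the growth rate per coalescent unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import log
from pathlib import Path

import numpy as np

from .alignment import Alignment, SequenceRecord, collapse_haplotypes
from .ancestral import AncestralEstimate, SiteFrequencySpectrum

BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimGenealogy:
    """A simulated haploid genealogy.

    ``edges`` holds one entry per branch as (descendant tip bitmask, length);
    ``merges`` records the merge history as (left node, right node, time) with
    node ids 0..n-1 for tips and n.. for internal nodes in merge order.
    """

    n: int
    model: str
    intervals: tuple[float, ...]  # while i = n, n-1, .., 2 lineages
    edges: tuple[tuple[int, float], ...]
    merges: tuple[tuple[int, int, float], ...]
    seed: int | None = None
    growth_rate: float = 0.0

    @property
    def tmrca(self) -> float:
        return float(sum(self.intervals))

    @property
    def total_branch_length(self) -> float:
        return float(sum(length for _m, length in self.edges))

    def to_newick(self, labels: list[str] | None = None) -> str:
        """Newick string with branch lengths in coalescent units."""
        labels = labels or [f"t{i + 1}" for i in range(self.n)]
        times = {i: 0.0 for i in range(self.n)}
        reprs = {i: labels[i] for i in range(self.n)}
        node = self.n
        for left, right, t in self.merges:
            bl_l = t - times[left]
            bl_r = t - times[right]
            reprs[node] = f"({reprs[left]}:{bl_l:.10g},{reprs[right]}:{bl_r:.10g})"
            times[node] = t
            node += 1
        return reprs[node - 1] + ";"


@dataclass
class SimDataset:
    """A simulated alignment with full generating ground truth."""

    alignment: Alignment
    genealogy: SimGenealogy
    ancestral_sequence: str
    true_sfs: SiteFrequencySpectrum
    mutated_positions: tuple[int, ...]  # 1-based
    outgroups: Alignment | None = None
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def truth_json(self) -> str:
        return json.dumps({
            "tmrca_coalescent_units": self.genealogy.tmrca,
            "sfs": list(self.true_sfs.counts),
            "mutated_positions": list(self.mutated_positions),
            "params": self.params,
            "seed": self.seed,
        }, indent=2)


# ---------------------------------------------------------------------------
# Genealogy simulation


def _coalescent_intervals(n: int, model: str, growth_rate: float,
                          rng: np.random.Generator) -> list[float]:
    """Intercoalescent interval durations while i = n..2 lineages exist."""
    intervals = []
    t = 0.0
    for i in range(n, 1, -1):
        rate = i * (i - 1) / 2.0
        s = rng.exponential(1.0 / rate)
        if model == "constant":
            w = s
        elif model == "exponential":
            if growth_rate == 0.0:
                w = s
            else:
                # solve int_t^{t+w} e^{rho x} dx = s
                rho = growth_rate
                w = log(np.exp(rho * t) + rho * s) / rho - t
        else:
            raise ValueError(f"unknown model {model!r}")
        intervals.append(w)
        t += w
    return intervals


def simulate_genealogy(n: int, model: str = "constant",
                       growth_rate: float = 0.0,
                       seed: int | np.random.Generator | None = None) -> SimGenealogy:
    """Simulate a Kingman genealogy for ``n`` haploid samples.

    ``model`` is 'constant' or 'exponential'; for the latter ``growth_rate``
    is the exponential growth rate per coalescent unit (rho >= 0).
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    if growth_rate < 0:
        raise ValueError("growth rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    intervals = _coalescent_intervals(n, model, growth_rate, rng)
    # active lineages: (node id, bitmask, birth time)
    active = [(i, 1 << i, 0.0) for i in range(n)]
    edges: list[tuple[int, float]] = []
    merges: list[tuple[int, int, float]] = []
    t = 0.0
    next_node = n
    for w in intervals:
        t += w
        a, b = rng.choice(len(active), size=2, replace=False)
        a, b = sorted((int(a), int(b)))
        (ida, ma, ta) = active[a]
        (idb, mb, tb) = active[b]
        edges.append((ma, t - ta))
        edges.append((mb, t - tb))
        merges.append((ida, idb, t))
        merged = (next_node, ma | mb, t)
        next_node += 1
        active = [x for k, x in enumerate(active) if k not in (a, b)] + [merged]
    seed_val = seed if isinstance(seed, int) else None
    return SimGenealogy(n=n, model=model, intervals=tuple(intervals),
                        edges=tuple(edges), merges=tuple(merges),
                        seed=seed_val, growth_rate=growth_rate)


# ---------------------------------------------------------------------------
# Mutations


def drop_mutations(gen: SimGenealogy, theta: float, L: int,
                   seed: int | np.random.Generator | None = None,
                   id_prefix: str = "s") -> SimDataset:
    """Drop infinite-sites mutations (rate theta/2 per lineage) on a genealogy.

    Each mutation hits a distinct site drawn without replacement from 1..L.
    Returns the ingroup alignment together with the true ancestral sequence
    and the true unfolded SFS.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ancestral = "".join(rng.choice(BASES, size=L))
    n = gen.n
    masks = []
    for mask, length in gen.edges:
        m = rng.poisson(theta / 2.0 * length)
        masks.extend([mask] * int(m))
    if len(masks) > L:
        raise ValueError(
            f"{len(masks)} mutations exceed {L} sites; increase L")
    positions = sorted(int(p) + 1 for p in
                       rng.choice(L, size=len(masks), replace=False))
    anc_arr = np.array(list(ancestral))
    mat = np.tile(anc_arr, (n, 1))
    xi = [0] * (n - 1)
    for pos, mask in zip(positions, masks):
        anc_base = ancestral[pos - 1]
        choices = [b for b in BASES if b != anc_base]
        derived = choices[int(rng.integers(3))]
        carriers = [i for i in range(n) if (mask >> i) & 1]
        mat[carriers, pos - 1] = derived
        xi[len(carriers) - 1] += 1
    records = tuple(SequenceRecord(f"{id_prefix}{i + 1:03d}", "".join(row))
                    for i, row in enumerate(mat))
    sfs = SiteFrequencySpectrum(tuple(xi), n, L_effective=L)
    return SimDataset(
        alignment=Alignment(records), genealogy=gen,
        ancestral_sequence=ancestral, true_sfs=sfs,
        mutated_positions=tuple(positions),
        params={"theta": theta, "L": L, "model": gen.model,
                "growth_rate": gen.growth_rate},
        seed=seed if isinstance(seed, int) else None)


# ---------------------------------------------------------------------------
# Outgroups


def _jc_evolve(sequence: str, d: float, rng: np.random.Generator) -> str:
    """Evolve a sequence for expected ``d`` substitutions/site (Jukes-Cantor).

    Multiple hits allowed: per site, P(end state != start) = 3/4 (1 - e^{-4d/3}),
    and a changed site is equally likely to be any of the three other bases.
    """
    p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    arr = np.array(list(sequence))
    change = rng.random(len(arr)) < p_change
    idx = np.where(change)[0]
    for i in idx:
        others = [b for b in BASES if b != arr[i]]
        arr[i] = others[int(rng.integers(3))]
    return "".join(arr)


def attach_outgroups(ds: SimDataset, divergence_years: list[float],
                     rate_per_site_year: float, generation_time: float,
                     theta: float | None = None,
                     seed: int | np.random.Generator | None = None) -> SimDataset:
    """Evolve outgroup sequences from the true ancestral sequence.

    Each outgroup at divergence T years accumulates 2 T rate expected
    substitutions per site relative to the ingroup ancestor (both lineages
    evolving).  Divergences must exceed the ingroup TMRCA in years.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = theta if theta is not None else ds.params.get("theta", 0.0)
    L = len(ds.ancestral_sequence)
    if theta > 0 and rate_per_site_year > 0:
        n_ef = theta / (2.0 * L * rate_per_site_year * generation_time)
        tmrca_years = ds.genealogy.tmrca * n_ef * generation_time
        for T in divergence_years:
            if T < tmrca_years:
                raise ValueError(
                    f"outgroup divergence {T:.0f} y below ingroup TMRCA "
                    f"{tmrca_years:.0f} y")
    records = []
    for k, T in enumerate(divergence_years):
        d = 2.0 * T * rate_per_site_year
        seq = _jc_evolve(ds.ancestral_sequence, d, rng)
        records.append(SequenceRecord(f"outgroup{k + 1}", seq,
                                      region="outgroup"))
    ds.outgroups = Alignment(tuple(records))
    ds.params.update({"outgroup_divergences_years": list(divergence_years),
                      "rate_per_site_year": rate_per_site_year,
                      "generation_time": generation_time})
    return ds


def true_ancestral_estimate(ds: SimDataset) -> AncestralEstimate:
    """Wrap the simulator's true ancestral sequence for downstream polarization."""
    L = len(ds.ancestral_sequence)
    return AncestralEstimate(ds.ancestral_sequence,
                             tuple(["both-outgroups-agree"] * L))


# ---------------------------------------------------------------------------
# Study-shaped presets

#: dataset shapes emulated by the generator; sample size, fragment length and
#: per-fragment theta follow the study conditions they mimic, the growth
#: variant uses the exponential-growth point estimate (rho = 10 per
#: coalescent unit) reported by the likelihood demographic analysis
PRESETS = {
    "study648": {"n": 76, "L": 648, "theta": 2.7, "model": "constant", "rho": 0.0},
    "study340": {"n": 50, "L": 340, "theta": 0.9, "model": "constant", "rho": 0.0},
    "growth": {"n": 76, "L": 648, "theta": 2.7, "model": "exponential", "rho": 10.0},
}

#: fossil-calibrated outgroup divergences (years): sister lineage ~4.6 Ma,
#: deeper outgroup ~9.5 Ma
DEFAULT_OUTGROUP_DIVERGENCES = (4.6e6, 9.5e6)
DEFAULT_RATE = 1e-8  # substitutions/site/year (1% per Ma)
DEFAULT_GENERATION_TIME = 9.2  # years

_REGIONS = ("RegionB", "RegionC", "RegionD", "RegionE")


def emulate_study(preset: str = "study648",
                  seed: int | None = None,
                  outgroups: bool = True) -> SimDataset:
    """One-call study-shaped dataset: ingroup + outgroups + region labels.

    The largest haplotype class is labelled as a single monomorphic
    subpopulation (up to 24 samples, mimicking a monomorphic regional sample);
    remaining samples are assigned round-robin to other region labels.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[preset]
    rng = np.random.default_rng(seed)
    gen = simulate_genealogy(p["n"], model=p["model"], growth_rate=p["rho"], seed=rng)
    ds = drop_mutations(gen, p["theta"], p["L"], seed=rng)
    if outgroups:
        attach_outgroups(ds, list(DEFAULT_OUTGROUP_DIVERGENCES),
                         DEFAULT_RATE, DEFAULT_GENERATION_TIME, seed=rng)
    table = collapse_haplotypes(ds.alignment)
    biggest = max(table.haplotypes, key=lambda h: h[2])
    mono_ids = set(biggest[3][:24])
    from dataclasses import replace
    new_records = []
    k = 0
    for rec in ds.alignment.records:
        if rec.id in mono_ids:
            region = "RegionA"
        else:
            region = _REGIONS[k % len(_REGIONS)]
            k += 1
        new_records.append(replace(rec, region=region, source=f"SIM:{preset}"))
    ds.alignment = Alignment(tuple(new_records))
    ds.params["preset"] = preset
    ds.seed = seed
    return ds


def write_dataset(ds: SimDataset, outdir: str | Path, stem: str = "sim") -> dict[str, Path]:
    """Serialize a dataset: FASTA (ingroup/outgroups), metadata TSV, truth JSON."""
    from .alignment import write_fasta, write_metadata
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"ingroup": outdir / f"{stem}_ingroup.fasta",
             "metadata": outdir / f"{stem}_metadata.tsv",
             "truth": outdir / f"{stem}_truth.json"}
    write_fasta(ds.alignment, paths["ingroup"])
    write_metadata(ds.alignment, paths["metadata"])
    paths["truth"].write_text(ds.truth_json())
    if ds.outgroups is not None:
        paths["outgroups"] = outdir / f"{stem}_outgroups.fasta"
        write_fasta(ds.outgroups, paths["outgroups"])
    return paths
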