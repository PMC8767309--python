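"""Statistical evaluation of a candidate site with six measures.

m1  mean bond quantile score over the site's bonds
m2  mean residue quantile score over the site's residues
m3  proportion of site bonds with score > 0.95
m4  mean reference bond score (requires a reference ensemble)
m5  proportion of site residues with score > 0.95
m6  mean reference residue score (requires a reference ensemble)

m1/m2 succeed when they exceed the upper bound of a 95% bootstrap
confidence interval built from 1,000 surrogate sites (same residue
count, strictly smaller diameter); m3/m5 succeed above the expected
proportion 0.05; m4/m6 succeed above the expected value 0.5.  All
comparisons are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from bondprop.graph_construction import AtomisticGraph
from bondprop.quantile_scoring import ScoreTable

__all__ = [
    "SiteScores",
    "MeasureReport",
    "SurrogateEnsemble",
    "site_scores",
    "measure_suite",
    "sample_surrogates",
    "bootstrap_ci",
    "verdicts",
    "aggregate_multi_site",
    "evaluate_site",
]

MEASURES = ("m1", "m2", "m3", "m4", "m5", "m6")
HIGH_SCORE = 0.95
EXPECTED_PROPORTION = 0.05
EXPECTED_REFERENCE = 0.5
DEFAULT_SURROGATE_SEED = 2021
DEFAULT_BOOTSTRAP_SEED = 2021


@dataclass
class SiteScores:
    """Scores of the bonds and residues belonging to one site.

    Site bonds are the scored bonds with at least one endpoint atom in
    the site's residues; edges touching non-protein (e.g. ligand) atoms
    are excluded, as are unscored (source) bonds.
    """

    residue_indices: tuple[int, ...]
    bond_scores: np.ndarray
    residue_scores: np.ndarray
    bond_ref_scores: np.ndarray | None = None
    residue_ref_scores: np.ndarray | None = None
    name: str = "site"

    @property
    def n_bonds(self) -> int:
        return int(self.bond_scores.size)

    @property
    def n_residues(self) -> int:
        return int(self.residue_scores.size)


def site_bond_ids(
    graph: AtomisticGraph, residue_indices: set[int], table: ScoreTable
) -> list[int]:
    wanted = set(residue_indices)
    out = []
    for b in graph.bonds:
        if graph.categories[b.i] != "protein" or graph.categories[b.j] != "protein":
            continue
        ri, rj = int(graph.residue_of[b.i]), int(graph.residue_of[b.j])
        if (ri in wanted or rj in wanted) and b.edge_id in table.bond:
            out.append(b.edge_id)
    return out


def site_scores(
    graph: AtomisticGraph,
    table: ScoreTable,
    residue_indices: set[int],
    name: str = "site",
) -> SiteScores:
    """Collect the bond/residue scores of a site from a protein's
    :class:`~bondprop.quantile_scoring.ScoreTable`."""
    res = sorted(r for r in residue_indices if r in table.residue)
    if not res:
        raise ValueError(f"{name}: no scored residues in site")
    bond_ids = site_bond_ids(graph, set(res), table)
    if not bond_ids:
        raise ValueError(f"{name}: no scored bonds in site")
    return SiteScores(
        residue_indices=tuple(res),
        bond_scores=np.array([table.bond[e] for e in bond_ids]),
        residue_scores=np.array([table.residue[r] for r in res]),
        bond_ref_scores=(
            np.array([table.bond_ref[e] for e in bond_ids])
            if table.bond_ref is not None
            else None
        ),
        residue_ref_scores=(
            np.array([table.residue_ref[r] for r in res])
            if table.residue_ref is not None
            else None
        ),
        name=name,
    )


@dataclass
class MeasureReport:
    """Values, surrogate/bootstrap context and verdicts of the six
    measures for one site (or an average over sites)."""

    values: dict[str, float | None]
    ci_m1: tuple[float, float] | None = None
    ci_m2: tuple[float, float] | None = None
    surrogate_mean_bond: float | None = None
    surrogate_mean_residue: float | None = None
    verdicts: dict[str, bool | None] = field(default_factory=dict)
    site_name: str = "site"

    @property
    def n_success(self) -> int:
        return sum(1 for v in self.verdicts.values() if v is True)

    @property
    def n_evaluated(self) -> int:
        return sum(1 for v in self.verdicts.values() if v is not None)

    def summary(self) -> str:
        rows = [f"site: {self.site_name}"]
        bounds = {
            "m1": self.ci_m1[1] if self.ci_m1 else None,
            "m2": self.ci_m2[1] if self.ci_m2 else None,
            "m3": EXPECTED_PROPORTION,
            "m4": EXPECTED_REFERENCE,
            "m5": EXPECTED_PROPORTION,
            "m6": EXPECTED_REFERENCE,
        }
        for m in MEASURES:
            val = self.values.get(m)
            if val is None:
                rows.append(f"  {m}: (not evaluated)")
                continue
            verdict = self.verdicts.get(m)
            tag = {True: "Success", False: "Failure", None: "-"}[verdict]
            bound = bounds[m]
            bound_txt = f" (> {bound:.3f})" if bound is not None else ""
            rows.append(f"  {m}: {val:.3f}{bound_txt} {tag}")
        rows.append(f"  detected by {self.n_success}/{self.n_evaluated} measures")
        return "\n".join(rows)


def measure_suite(scores: SiteScores) -> MeasureReport:
    """Compute the six measure values (verdicts filled later); m4/m6
    are omitted when no reference scores are present."""
    values: dict[str, float | None] = {
        "m1": float(scores.bond_scores.mean()),
        "m2": float(scores.residue_scores.mean()),
        "m3": float(np.mean(scores.bond_scores > HIGH_SCORE)),
        "m4": (
            float(scores.bond_ref_scores.mean())
            if scores.bond_ref_scores is not None
            else None
        ),
        "m5": float(np.mean(scores.residue_scores > HIGH_SCORE)),
        "m6": (
            float(scores.residue_ref_scores.mean())
            if scores.residue_ref_scores is not None
            else None
        ),
    }
    return MeasureReport(values=values, site_name=scores.name)


@dataclass
class SurrogateEnsemble:
    """Random sites matching the candidate's residue count with
    strictly smaller diameter, and their mean scores."""

    sites: list[tuple[int, ...]]
    mean_bond_scores: np.ndarray
    mean_residue_scores: np.ndarray
    seed: int
    site_diameter: float


def site_diameter(graph: AtomisticGraph, residue_indices: set[int]) -> float:
    """Maximum atom-atom distance over the protein atoms of the site's
    residues (ligand atoms excluded)."""
    members = graph.atoms_of_residue()
    atoms = np.concatenate(
        [
            [i for i in members[r] if graph.categories[i] == "protein"]
            for r in sorted(residue_indices)
        ]
    ).astype(int)
    if atoms.size < 2:
        return 0.0
    return float(pdist(graph.coords[atoms]).max())


def sample_surrogates(
    graph: AtomisticGraph,
    table: ScoreTable,
    residue_indices: set[int],
    n_sites: int = 1000,
    seed: int = DEFAULT_SURROGATE_SEED,
    max_restarts: int = 10_000,
) -> SurrogateEnsemble:
    """Rejection-sample ``n_sites`` surrogate sites.

    Growth sampler: a uniformly random seed residue, then repeated
    uniform draws among the residues whose addition keeps the running
    diameter strictly below the candidate site's, until the residue
    count matches; dead ends restart the site (capped overall).
    """
    unknown = {r for r in residue_indices if not 0 <= r < graph.n_residues}
    if unknown:
        raise ValueError(f"site names unknown residues: {sorted(unknown)[:5]}")
    size = len(residue_indices)
    diameter = site_diameter(graph, residue_indices)
    members = graph.atoms_of_residue()
    candidates = [
        r
        for r in range(graph.n_residues)
        if r in table.residue
        and graph.residue_category(r) == "protein"
        and len(members[r]) > 0
    ]
    if len(candidates) < size:
        raise ValueError(
            f"only {len(candidates)} candidate residues for sites of {size}"
        )
    coords_of = {
        r: graph.coords[
            [i for i in members[r] if graph.categories[i] == "protein"]
        ]
        for r in candidates
    }
    internal_diam = {
        r: (float(pdist(c).max()) if len(c) > 1 else 0.0)
        for r, c in coords_of.items()
    }
    feasible_seeds = [r for r in candidates if internal_diam[r] < diameter]
    if not feasible_seeds:
        raise ValueError(
            "no single residue fits inside the candidate site diameter "
            f"({diameter:.2f} Å)"
        )

    rng = np.random.default_rng(seed)
    cand_arr = np.array(candidates)
    sites: list[tuple[int, ...]] = []
    mean_b: list[float] = []
    mean_r: list[float] = []
    restarts = 0
    while len(sites) < n_sites:
        chosen = [feasible_seeds[rng.integers(len(feasible_seeds))]]
        cloud = coords_of[chosen[0]]
        while len(chosen) < size:
            feasible = []
            for r in cand_arr:
                r = int(r)
                if r in chosen or internal_diam[r] >= diameter:
                    continue
                if cdist(coords_of[r], cloud).max() >= diameter:
                    continue
                feasible.append(r)
            if not feasible:
                restarts += 1
                if restarts > max_restarts:
                    raise RuntimeError(
                        f"surrogate sampling exceeded {max_restarts} restarts; "
                        f"diameter rule ({diameter:.2f} Å) too tight for "
                        f"sites of {size} residues"
                    )
                break
            pick = int(feasible[rng.integers(len(feasible))])
            chosen.append(pick)
            cloud = np.vstack([cloud, coords_of[pick]])
        else:
            bond_ids = site_bond_ids(graph, set(chosen), table)
            if not bond_ids:
                restarts += 1
                if restarts > max_restarts:
                    raise RuntimeError(
                        "surrogate sampling kept hitting bond-less sites"
                    )
                continue
            sites.append(tuple(sorted(chosen)))
            mean_b.append(float(np.mean([table.bond[e] for e in bond_ids])))
            mean_r.append(float(np.mean([table.residue[r] for r in chosen])))
    return SurrogateEnsemble(
        sites=sites,
        mean_bond_scores=np.array(mean_b),
        mean_residue_scores=np.array(mean_r),
        seed=seed,
        site_diameter=diameter,
    )


def bootstrap_ci(
    surrogate_means: np.ndarray,
    n_resamples: int = 10_000,
    level: float = 0.95,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean (resampling with
    replacement)."""
    values = np.asarray(surrogate_means, dtype=float)
    if values.size < 2:
        if values.size == 1:
            return (float(values[0]), float(values[0]))
        raise ValueError("need at least one surrogate mean")
    if np.ptp(values) == 0:
        return (float(values[0]), float(values[0]))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
    return (float(lower), float(upper))


def verdicts(
    report: MeasureReport,
    ci_m1: tuple[float, float] | None,
    ci_m2: tuple[float, float] | None,
) -> MeasureReport:
    """Fill verdicts: m1/m2 succeed above the CI upper bound, m3/m5
    above 0.05, m4/m6 above 0.5; all strictly."""
    report.ci_m1 = ci_m1
    report.ci_m2 = ci_m2

    def against(value: float | None, bound: float | None) -> bool | None:
        if value is None or bound is None:
            return None
        return bool(value > bound)

    report.verdicts = {
        "m1": against(report.values.get("m1"), ci_m1[1] if ci_m1 else None),
        "m2": against(report.values.get("m2"), ci_m2[1] if ci_m2 else None),
        "m3": against(report.values.get("m3"), EXPECTED_PROPORTION),
        "m4": against(report.values.get("m4"), EXPECTED_REFERENCE),
        "m5": against(report.values.get("m5"), EXPECTED_PROPORTION),
        "m6": against(report.values.get("m6"), EXPECTED_REFERENCE),
    }
    return report


def aggregate_multi_site(
    reports: list[MeasureReport],
    cis: list[tuple[tuple[float, float] | None, tuple[float, float] | None]]
    | None = None,
) -> MeasureReport:
    """Average the measure values (and m1/m2 CI bounds) over several
    sites of one structure and apply verdicts to the averages."""
    if not reports:
        raise ValueError("no reports to aggregate")
    if cis is None:
        cis = [(r.ci_m1, r.ci_m2) for r in reports]
    values: dict[str, float | None] = {}
    for m in MEASURES:
        vals = [r.values.get(m) for r in reports]
        present = [v for v in vals if v is not None]
        values[m] = float(np.mean(present)) if len(present) == len(vals) else None

    def mean_ci(which: int) -> tuple[float, float] | None:
        pairs = [c[which] for c in cis]
        if any(p is None for p in pairs):
            return None
        lows, highs = zip(*pairs)
        return (float(np.mean(lows)), float(np.mean(highs)))

    merged = MeasureReport(
        values=values,
        site_name=" + ".join(r.site_name for r in reports),
    )
    return verdicts(merged, mean_ci(0), mean_ci(1))


def evaluate_site(
    graph: AtomisticGraph,
    table: ScoreTable,
    residue_indices: set[int],
    name: str = "site",
    n_surrogates: int = 1000,
    surrogate_seed: int = DEFAULT_SURROGATE_SEED,
    n_resamples: int = 10_000,
    bootstrap_seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> tuple[MeasureReport, SurrogateEnsemble]:
    """Measures + surrogate ensemble + bootstrap CIs + verdicts for one
    candidate site."""
    scores = site_scores(graph, table, residue_indices, name=name)
    report = measure_suite(scores)
    ensemble = sample_surrogates(
        graph, table, residue_indices, n_sites=n_surrogates, seed=surrogate_seed
    )
    ci1 = bootstrap_ci(
        ensemble.mean_bond_scores, n_resamples=n_resamples, seed=bootstrap_seed
    )
    ci2 = bootstrap_ci(
        ensemble.mean_residue_scores, n_resamples=n_resamples, seed=bootstrap_seed
    )
    report.surrogate_mean_bond = float(ensemble.mean_bond_scores.mean())
    report.surrogate_mean_residue = float(ensemble.mean_residue_scores.mean())
    return verdicts(report, ci1, ci2), ensemble
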