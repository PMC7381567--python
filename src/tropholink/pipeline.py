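"""End-to-end analysis: build (or load) matrices, run every battery, emit tables.

:class:`TrophicNicheAnalysis` is the model-like entry point: construct it
from a simulated/loaded community bundle (raw specimen data) or directly
from pre-computed dissimilarity matrices (the archived-matrix reproduction
mode), then call :meth:`~TrophicNicheAnalysis.run` to obtain an
:class:`AnalysisReport` carrying

* the partial-Mantel battery over the six unordered dataset pairs,
  site-conditioned, plus the four simple Mantels against the site contrast;
* linkage selection and dendrograms per matrix, topological-similarity
  scores for the six pairs (all species and per site);
* Brownian/Abouheif phylogenetic-signal distributions for the morphology,
  diet and isotope dendrograms (all species and per site, isotopes
  re-standardised within site);
* the constrained-ordination battery (RDA for the isotope response, db-RDA
  for distance responses), forward-selected and conditioned on site;
* trophic-guild assignments.

Every stochastic stage draws from a named child stream of one seed, so a
report is reproducible bit-for-bit and the stages are insensitive to each
other's draw counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import similarity as sim
from .data_model import DissimilarityMatrix, PhylogeneticTree, ValidationError, align_matrices
from .dendrograms import Dendrogram, linkage_cluster, nye_topological_similarity, select_linkage
from .matrix_tests import mantel, partial_mantel
from .ordination import db_rda_fit, forward_select, pcoa, rda_fit, select_axes
from .phylo_signal import BMParams, dendrogram_signal_distribution

__all__ = ["PipelineOptions", "TrophicNicheAnalysis", "AnalysisReport"]

BIO_KINDS = ("phylogeny", "morphology", "diet", "isotope")
PAIRS = [("phylogeny", "morphology"), ("phylogeny", "diet"), ("phylogeny", "isotope"),
         ("morphology", "diet"), ("morphology", "isotope"), ("diet", "isotope")]
#: directed ordination comparisons: (predictor, response)
DIRECTED = [("phylogeny", "morphology"), ("phylogeny", "diet"), ("phylogeny", "isotope"),
            ("morphology", "diet"), ("morphology", "isotope"), ("diet", "isotope")]

_STAGE_IDS = {"diet": 11, "mantel": 23, "signal": 37, "ordination": 53}


def _stage_rng(seed, stage: str) -> np.random.Generator:
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_IDS[stage]]))


@dataclass
class PipelineOptions:
    """Stage sizes and the master seed (defaults sized for a full analysis)."""

    seed: int | None = 0
    rarefaction_target: int = 16
    rarefaction_iterations: int = 1000
    mantel_permutations: int = 10000
    signal_reps: int = 10000
    ordination_permutations: int = 10000
    alpha: float = 0.05
    per_site: bool = True
    n_axes: dict = field(default_factory=dict)   # kind -> axis count; else scree
    bm_variance: float = 0.1


@dataclass
class AnalysisReport:
    mantel_table: pd.DataFrame
    site_mantel_table: pd.DataFrame
    linkage_table: pd.DataFrame
    nye_table: pd.DataFrame
    signal_table: pd.DataFrame
    ordination_table: pd.DataFrame
    trophic_groups: pd.Series | None
    dendrograms: dict
    manifest: dict

    def summary(self) -> str:
        parts = ["Partial Mantel (site-conditioned):", self.mantel_table.to_string(index=False),
                 "", "Mantel vs site contrast:", self.site_mantel_table.to_string(index=False),
                 "", "Topological similarity (Nye score):", self.nye_table.to_string(index=False),
                 "", "Phylogenetic signal (Abouheif C_mean of BM tip states):",
                 self.signal_table.to_string(index=False),
                 "", "Constrained ordinations (site-conditioned):",
                 self.ordination_table.to_string(index=False)]
        return "\n".join(parts)

    def to_directory(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.mantel_table.to_csv(out / "partial_mantel.csv", index=False)
        self.site_mantel_table.to_csv(out / "site_mantel.csv", index=False)
        self.linkage_table.to_csv(out / "linkage_selection.csv", index=False)
        self.nye_table.to_csv(out / "topological_similarity.csv", index=False)
        self.signal_table.to_csv(out / "phylogenetic_signal.csv", index=False)
        self.ordination_table.to_csv(out / "ordination.csv", index=False)
        if self.trophic_groups is not None:
            self.trophic_groups.rename("trophic_group").to_csv(out / "trophic_groups.csv",
                                                               index_label="species_id")
        for name, dend in self.dendrograms.items():
            dend.write_newick(out / f"dendrogram_{name}.nwk")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2,
                                                      default=str) + "\n")


class TrophicNicheAnalysis:
    """The full phylogeny/morphology/diet/isotope correlation analysis."""

    def __init__(self, matrices: dict, species_table: pd.DataFrame,
                 phylogeny: PhylogeneticTree | None = None,
                 isotope_records: pd.DataFrame | None = None,
                 diet=None, hierarchy=None,
                 options: PipelineOptions | None = None):
        self.options = options or PipelineOptions()
        missing = sorted(set(BIO_KINDS) - set(matrices))
        if missing:
            raise ValidationError(f"missing matrices: {missing}")
        self.species_table = species_table
        site = sim.site_contrast_matrix(species_table)
        aligned = align_matrices(*[matrices[k] for k in BIO_KINDS], site)
        self.matrices = dict(zip(BIO_KINDS, aligned[:4]))
        self.site_matrix = aligned[4]
        self.labels = self.site_matrix.labels
        self.phylogeny = phylogeny
        self.isotope_records = isotope_records
        self.diet = diet
        self.hierarchy = hierarchy

    # ------------------------------------------------------------------
    @classmethod
    def from_bundle(cls, bundle, options: PipelineOptions | None = None,
                    graft_placements: dict | None = None) -> "TrophicNicheAnalysis":
        """Build all four matrices from raw bundle data."""
        options = options or PipelineOptions()
        tree = bundle.tree
        if graft_placements:
            tree = sim.graft_missing_taxa(tree, graft_placements)
        plan = sim.RarefactionPlan(target_n=options.rarefaction_target,
                                   n_iterations=options.rarefaction_iterations)
        matrices = {
            "phylogeny": sim.cophenetic_distance(tree),
            "morphology": sim.gower_distance(sim.size_standardize(bundle.morpho)),
            "diet": sim.hierarchical_diet_distance(
                bundle.diet, bundle.hierarchy, plan,
                rng=_stage_rng(options.seed, "diet")),
            "isotope": sim.isotope_distance(bundle.isotopes),
        }
        return cls(matrices, bundle.species, phylogeny=tree,
                   isotope_records=bundle.isotopes, diet=bundle.diet,
                   hierarchy=bundle.hierarchy, options=options)

    @classmethod
    def from_matrix_files(cls, paths: dict, species_table: pd.DataFrame,
                          phylogeny: PhylogeneticTree | None = None,
                          options: PipelineOptions | None = None) -> "TrophicNicheAnalysis":
        """Pre-computed-matrix mode: ``paths`` maps kind -> labelled square CSV."""
        matrices = {k: DissimilarityMatrix.from_csv(p, kind=k) for k, p in paths.items()}
        return cls(matrices, species_table, phylogeny=phylogeny, options=options)

    # ------------------------------------------------------------------
    def _sites(self) -> dict:
        sites = self.species_table.set_index("species_id")["site_id"]
        sites = sites.loc[list(self.labels)]
        return {s: sorted(sites.index[sites == s]) for s in sorted(sites.unique())}

    def _scoped_matrix(self, kind: str, scope: str, members) -> DissimilarityMatrix | None:
        if scope == "all":
            return self.matrices[kind]
        if len(members) < 4:
            return None
        if kind == "isotope" and self.isotope_records is not None:
            recs = self.isotope_records[self.isotope_records["species_id"].isin(members)]
            return sim.isotope_distance(recs)
        return self.matrices[kind].restrict(members)

    def run(self) -> AnalysisReport:
        opt = self.options
        rng_m = _stage_rng(opt.seed, "mantel")
        rng_s = _stage_rng(opt.seed, "signal")
        rng_o = _stage_rng(opt.seed, "ordination")

        # --- Mantel battery -------------------------------------------------
        mrows = []
        for a, b in PAIRS:
            res = partial_mantel(self.matrices[a], self.matrices[b], self.site_matrix,
                                 n_perm=opt.mantel_permutations, rng=rng_m)
            mrows.append({"pair": f"{a}~{b}", "r": res.r, "p": res.p,
                          "n_perm": res.n_perm, "n_species": res.n})
        srows = []
        for a in BIO_KINDS:
            res = mantel(self.matrices[a], self.site_matrix,
                         n_perm=opt.mantel_permutations, rng=rng_m)
            srows.append({"matrix": a, "r": res.r, "p": res.p,
                          "n_perm": res.n_perm, "n_species": res.n})

        # --- dendrograms & topology ----------------------------------------
        sites = self._sites()
        scopes = ["all"] + (sorted(sites) if opt.per_site else [])
        lrows, dendros = [], {}
        for scope in scopes:
            members = self.labels if scope == "all" else sites[scope]
            for kind in BIO_KINDS:
                m = self._scoped_matrix(kind, scope, members)
                if m is None:
                    continue
                method, dend, table = select_linkage(m)
                dendros[(kind, scope)] = dend
                best = table.loc[table["method"] == method, "cophenetic_correlation"].iloc[0]
                lrows.append({"matrix": kind, "scope": scope, "method": method,
                              "cophenetic_correlation": best})
        nrows = []
        for a, b in PAIRS:
            row = {"comparison": f"{a}~{b}"}
            for scope in scopes:
                da, db = dendros.get((a, scope)), dendros.get((b, scope))
                row[scope] = (np.nan if da is None or db is None
                              else nye_topological_similarity(da, db).score)
            nrows.append(row)

        # --- phylogenetic signal -------------------------------------------
        grows = []
        if self.phylogeny is not None:
            params = BMParams(instantaneous_variance=opt.bm_variance,
                              n_reps=opt.signal_reps)
            for scope in scopes:
                members = self.labels if scope == "all" else sites[scope]
                phylo = (self.phylogeny if scope == "all"
                         else self.phylogeny.prune_to(members)) if len(members) >= 4 else None
                for kind in ("morphology", "diet", "isotope"):
                    dend = dendros.get((kind, scope))
                    if dend is None or phylo is None:
                        continue
                    dist = dendrogram_signal_distribution(dend, phylo, params, rng=rng_s)
                    grows.append({"dendrogram": kind, "scope": scope,
                                  "cmean_mean": dist.mean, "q2.5": dist.q2_5,
                                  "q97.5": dist.q97_5, "n_reps": opt.signal_reps})

        # --- trophic guilds --------------------------------------------------
        groups = None
        if self.diet is not None and self.hierarchy is not None:
            groups = sim.classify_species_trophic_groups(self.diet, self.hierarchy)
            groups = groups.loc[[s for s in groups.index if s in self.labels]]

        # --- constrained ordinations ----------------------------------------
        site_series = self.species_table.set_index("species_id")["site_id"].loc[list(self.labels)]
        site_col = pd.DataFrame(
            {"site": (site_series == sorted(site_series.unique())[0]).astype(float)})
        site_col.index = list(self.labels)
        condition = site_col if site_col["site"].nunique() > 1 else None
        embeddings = {k: pcoa(self.matrices[k]) for k in ("phylogeny", "morphology", "diet")}
        axis_tables = {}
        for k, emb in embeddings.items():
            axes = select_axes(emb, n_axes=opt.n_axes.get(k))
            axis_tables[k] = emb.coordinates[axes]
        iso_response = None
        if self.isotope_records is not None:
            means = sim.species_isotope_means(
                self.isotope_records[self.isotope_records["species_id"].isin(self.labels)])
            iso_response = (means - means.mean()) / means.std(ddof=1)
        orows = []
        for pred, resp in DIRECTED:
            cand = axis_tables[pred]
            if resp == "isotope":
                if iso_response is None:
                    # fall back to the embedding of the isotope distance matrix
                    emb = pcoa(self.matrices["isotope"])
                    response = emb.coordinates
                else:
                    response = iso_response.loc[list(self.labels)]
                selected = forward_select(response, cand, alpha=opt.alpha,
                                          n_perm=opt.ordination_permutations,
                                          condition=condition, rng=rng_o)
                fit = (rda_fit(response, cand[selected], condition=condition)
                       if selected else None)
            else:
                response = self.matrices[resp]
                selected = forward_select(response, cand, alpha=opt.alpha,
                                          n_perm=opt.ordination_permutations,
                                          condition=condition, rng=rng_o)
                fit = (db_rda_fit(response, cand[selected], condition=condition)
                       if selected else None)
            row = {"predictor": pred, "response": resp,
                   "selected_axes": ";".join(selected)}
            if fit is None:
                row.update({"F": np.nan, "df1": 0, "df2": np.nan, "R2": 0.0,
                            "adj_R2": 0.0, "p": np.nan})
            else:
                from .ordination import anova_permutation
                p = anova_permutation(fit, n_perm=opt.ordination_permutations, rng=rng_o)
                row.update({"F": fit.F, "df1": fit.df[0], "df2": fit.df[1],
                            "R2": fit.R2, "adj_R2": fit.adj_R2, "p": p})
            orows.append(row)

        manifest = {"seed": opt.seed, "options": asdict(opt),
                    "n_species": len(self.labels), "scopes": scopes,
                    "stage_streams": _STAGE_IDS}
        return AnalysisReport(
            mantel_table=pd.DataFrame(mrows),
            site_mantel_table=pd.DataFrame(srows),
            linkage_table=pd.DataFrame(lrows),
            nye_table=pd.DataFrame(nrows),
            signal_table=pd.DataFrame(grows),
            ordination_table=pd.DataFrame(orows),
            trophic_groups=groups,
            dendrograms={f"{k}_{s}": d for (k, s), d in dendros.items()},
            manifest=manifest)
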