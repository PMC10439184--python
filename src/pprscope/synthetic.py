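"""Seeded synthetic communities with planted, recoverable structure.

The generator emulates the sampling design the analysis assumes -- 2
stations x 3 photic-zone depths (SUR/DCM/BOT) x 2 size fractions x 2
replicates = 24 libraries over 12 water samples -- and plants exactly the
features the pipeline is supposed to recover:

* unigene protein sequences derived from reference rhodopsins by seeded
  point mutation, with the spectral-tuning site protected so the planted
  blue/green label stays readable;
* per-fraction TPM matrices with log-normal per-unigene abundances, a
  planted prokaryote/eukaryote share of the merged rhodopsin pool, and
  monotone depth trends for blue vs green absorbers;
* per-fraction RNA yields per liter;
* an environmental table whose nutrient variables are coupled to the
  realized eukaryotic PPR community gradient at a chosen distance-level
  association strength (log-normal-style marginals);
* a 16S/18S-style relative-abundance table coupled to each taxon's merged
  PPR expression.

Everything is reproducible bit-for-bit under the config seed, and the
ground truth used for generation ships with the fixture bundle.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .panel import PanelIndex, ReferenceRhodopsin, load_panel
from .classify import classify_spectral
from .quantify import merge_fractions

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: codon used per amino acid for back-translation (uniform synonymous codons
#: would break byte-determinism across numpy versions less simply; a fixed
#: codon table keeps nucleotide fixtures deterministic and is sufficient for
#: exercising ORF translation)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    "X": "NNN",
}


def _bray_curtis(values: np.ndarray) -> np.ndarray:
    """Plain double-loop Bray-Curtis (generator-internal, independent of the
    analysis modules so planted structure never depends on the code under
    test)."""
    n = len(values)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = values[i].sum() + values[j].sum()
            d = np.abs(values[i] - values[j]).sum() / denom if denom else 0.0
            out[i, j] = out[j, i] = d
    return out


def _pcoa_axis1(dist: np.ndarray) -> np.ndarray:
    """First principal coordinate (classical MDS) of a distance matrix."""
    n = len(dist)
    centering = np.eye(n) - np.full((n, n), 1.0 / n)
    gower = -0.5 * centering @ (dist**2) @ centering
    eigvals, eigvecs = np.linalg.eigh(gower)
    return eigvecs[:, -1] * np.sqrt(max(eigvals[-1], 0.0))


def _calibrate_mixing_weight(
    rho_distance: float,
    euk_bc: np.ndarray,
    u_scores: np.ndarray,
    eps: np.ndarray,
    log_sds: np.ndarray,
) -> float:
    """Copula mixing weight delivering a planted distance-level association.

    The nutrient latents are ``w * u + sqrt(1 - w^2) * eps`` (unit-variance
    Gaussians for every ``w``).  Pairwise distances shrink and distort the
    value-level correlation ``w`` in ways that depend on the realized
    community matrix, so ``w`` is solved numerically such that the Pearson
    correlation between the community distance triangle and the z-scored
    Euclidean nutrient distance triangle equals ``rho_distance`` -- i.e. the
    generator plants the association on the scale a Mantel test estimates.
    Returns the best achievable weight (1.0) when the target is out of
    reach for this realization.
    """
    n = len(u_scores)
    iu = np.triu_indices(n, k=1)
    d_bc = euk_bc[iu]

    def realized(w: float) -> float:
        latent = w * u_scores[:, None] + np.sqrt(1 - w**2) * eps
        values = np.exp(log_sds[None, :] * latent)  # the emitted marginals
        z = (values - values.mean(axis=0)) / values.std(axis=0, ddof=1)
        sq = ((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2)
        d_env = np.sqrt(sq)[iu]
        return float(np.corrcoef(d_bc, d_env)[0, 1])

    lo, hi = 0.0, 1.0 - 1e-9
    if realized(hi) <= rho_distance:
        return 1.0
    if realized(lo) >= rho_distance:
        return 0.0
    from scipy.optimize import brentq

    return float(brentq(lambda w: realized(w) - rho_distance, lo, hi, xtol=1e-6))


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the synthetic community; defaults are the study conditions.

    ``divergence_pct`` is the per-site substitution probability (x100)
    outside protected sites.  ``planted_shares`` fixes each domain's share of
    the merged rhodopsin pool per water sample.  ``env_effect_r`` is the
    planted eukaryote-PPR/nutrient association on the distance-matrix scale
    (the correlation a Mantel test estimates); the eukaryote composition
    responds to a latent gradient with an e-fold tilt of ``env_tilt`` per
    gradient SD, and the nutrient coupling is calibrated per realization to
    deliver the requested distance-level correlation.
    ``share_mode='exact'`` rescales group sums so the merged share is
    exact; ``'noisy'`` adds multiplicative log-normal noise (sigma
    ``share_noise_sigma``) afterwards so shares hold only up to sampling
    noise.
    """

    seed: int = 0
    n_unigenes: int = 500
    divergence_pct: float = 10.0
    planted_shares: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"prokaryote": 0.7, "eukaryote": 0.3}
    )
    share_mode: str = "exact"  # exact | noisy
    share_noise_sigma: float = 0.05
    depth_trend: Mapping[str, str] = dataclasses.field(
        default_factory=lambda: {"BPR": "increasing", "GPR": "decreasing"}
    )
    depth_trend_fold: float = 3.0
    env_effect_r: float = 0.6
    env_tilt: float = 1.0
    abundance_effect_r: float = 0.9
    tpm_lognormal_mu: float = 3.0
    tpm_lognormal_sigma: float = 1.5
    sample_noise_sigma: float = 0.4
    rna_yield_range: tuple[float, float] = (0.2, 2.0)
    truncated_fraction: float = 0.0
    stations: tuple[str, ...] = ("C6", "C9")
    depth_layers: tuple[str, ...] = ("SUR", "DCM", "BOT")
    replicates: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence_pct <= 50.0:
            raise ValueError("divergence_pct must lie in [0, 50]")
        total = sum(self.planted_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"planted_shares must sum to 1, got {total}")
        if any(v < 0 for v in self.planted_shares.values()):
            raise ValueError("planted shares must be non-negative")
        if not 0.0 <= self.env_effect_r <= 1.0:
            raise ValueError("env_effect_r must lie in [0, 1]")
        if self.rna_yield_range[0] <= 0:
            raise ValueError("RNA yields must be positive")
        if self.share_mode not in ("exact", "noisy"):
            raise ValueError("share_mode must be 'exact' or 'noisy'")
        if not 0.0 <= self.truncated_fraction <= 0.5:
            raise ValueError("truncated_fraction must lie in [0, 0.5]")


@dataclasses.dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    unigenes: pd.DataFrame  # per-unigene source/labels
    merged_group_sums: pd.DataFrame  # water samples x domains, post-merge
    fraction_group_sums: pd.DataFrame  # long: sample_id x domain sums
    gradient: pd.Series  # latent nutrient gradient per water sample
    env_coefficients: dict  # generating copula parameters


@dataclasses.dataclass
class SyntheticCommunity:
    """Fixture bundle: sequences, tables, and generating ground truth."""

    config: SimulationConfig
    aa_seqs: dict[str, str]
    nt_seqs: dict[str, str]
    tpm_small: pd.DataFrame
    tpm_large: pd.DataFrame
    sample_meta: pd.DataFrame
    env: pd.DataFrame
    taxon_abundance: pd.DataFrame
    ground_truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        """Write the bundle as plain-text files (deterministic bytes)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_fasta(outdir / "unigenes.faa", self.aa_seqs)
        _write_fasta(outdir / "unigenes.fna", self.nt_seqs)
        kw = dict(sep="\t", float_format="%.10g", lineterminator="\n")
        self.tpm_small.rename_axis("unigene_id").to_csv(
            outdir / "tpm_small.tsv", **kw
        )
        self.tpm_large.rename_axis("unigene_id").to_csv(
            outdir / "tpm_large.tsv", **kw
        )
        self.sample_meta.to_csv(outdir / "sample_meta.tsv", index=False, **kw)
        self.env.rename_axis("water_sample_id").to_csv(outdir / "env.tsv", **kw)
        self.taxon_abundance.rename_axis("water_sample_id").to_csv(
            outdir / "taxon_abundance.tsv", **kw
        )
        self.ground_truth.unigenes.to_csv(
            outdir / "ground_truth_unigenes.tsv", index=False, **kw
        )
        cfg = dataclasses.asdict(self.config)
        cfg["planted_shares"] = dict(cfg["planted_shares"])
        cfg["depth_trend"] = dict(cfg["depth_trend"])
        (outdir / "config.json").write_text(
            json.dumps(cfg, indent=2, sort_keys=True) + "\n"
        )


def _write_fasta(path: Path, seqs: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def mutate_sequence(
    seq: str,
    divergence_pct: float,
    protect_sites: Iterable[int] = (),
    rng: np.random.Generator | int | None = None,
) -> str:
    """Substitute each unprotected site with probability ``divergence_pct``/100.

    A substituted site receives a uniformly random *different* canonical
    residue.  ``protect_sites`` are 1-based positions left untouched.
    Deterministic under a seeded generator.
    """
    if not 0.0 <= divergence_pct <= 100.0:
        raise ValueError("divergence_pct must lie in [0, 100]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    protect = set(protect_sites)
    bad = [p for p in protect if not 1 <= p <= len(seq)]
    if bad:
        raise ValueError(f"protected sites outside sequence: {bad}")
    letters = np.array(list(seq))
    hit = rng.random(len(letters)) < divergence_pct / 100.0
    for p in protect:
        hit[p - 1] = False
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = AA20[AA20 != letters[i]]
        letters[i] = rng.choice(choices)
    return "".join(letters)


def mutate_reference(
    ref: ReferenceRhodopsin,
    divergence_pct: float,
    protect_sites: Iterable[int] | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[str, dict]:
    """Mutant of a panel entry plus its ground-truth record.

    By default the tuning site (when present) is protected so the planted
    spectral class survives mutation.
    """
    if protect_sites is None:
        protect_sites = [ref.tuning_site] if ref.tuning_site is not None else []
    seq = mutate_sequence(ref.protein_seq, divergence_pct, protect_sites, rng)
    residue = (
        seq[ref.tuning_site - 1] if ref.tuning_site is not None else None
    )
    spectral, lam = classify_spectral(residue, ref.family, ref.is_ppr)
    truth = {
        "source_ref_id": ref.ref_id,
        "family": ref.family,
        "is_ppr": ref.is_ppr,
        "domain": ref.domain,
        "taxon": ref.taxon,
        "supergroup": ref.supergroup,
        "tuning_residue": residue,
        "spectral_class": spectral,
        "lambda_max_nm": lam,
    }
    return seq, truth


def back_translate(aa_seq: str) -> str:
    """Nucleotide coding sequence for a protein (fixed codon per residue)."""
    return "".join(_CODON[a] for a in aa_seq) + "TAA"


def _source_weights(panel: PanelIndex) -> tuple[list[str], np.ndarray]:
    """Sampling weights over panel entries emulating the observed pool:

    mostly prokaryotic PR/XR, some BR-like, a sprinkle of sensory rhodopsin,
    and a dinoflagellate-dominated eukaryotic PR contingent (~28% of
    unigenes).
    """
    family_w = {
        "PR": 3.0, "XR": 0.35, "GR": 1.0, "BR": 0.5,
        "ActR": 0.5, "ESR": 0.5, "SRI": 0.3, "other_rhodopsin": 0.0,
    }
    ids, weights = [], []
    for entry in panel:
        if entry.domain == "virus":
            continue
        ids.append(entry.ref_id)
        weights.append(family_w[entry.family])
    w = np.array(weights)
    dom = np.array([panel[i].domain for i in ids])
    target = {"prokaryote": 0.72, "eukaryote": 0.28}
    for d, t in target.items():
        mask = dom == d
        w[mask] = w[mask] / w[mask].sum() * t
    return ids, w / w.sum()


def _truncate(seq: str, span: tuple[int, int], rng: np.random.Generator) -> str:
    """Drop an N-terminal piece ending inside the helix C--F span."""
    start, end = span
    hi = min(start + 40, (start + end) // 2)
    cut = int(rng.integers(start + 4, hi))  # 0-based keep-from index
    return seq[cut:]


def simulate_community(
    config: SimulationConfig, panel: PanelIndex | None = None
) -> SyntheticCommunity:
    """Generate a full fixture bundle with the planted structure above."""
    if panel is None:
        panel = load_panel()
    rng = np.random.default_rng(config.seed)

    # ---- sampling design and RNA yields -------------------------------
    water_samples = [
        f"{st}_{dp}_{rep}"
        for st in config.stations
        for dp in config.depth_layers
        for rep in range(1, config.replicates + 1)
    ]
    depth_index = {
        ws: config.depth_layers.index(ws.split("_")[1]) for ws in water_samples
    }
    lo, hi = config.rna_yield_range
    meta_rows = []
    for ws in water_samples:
        st, dp, rep = ws.split("_")
        for frac, tag in (("small", "S"), ("large", "L")):
            meta_rows.append(
                {
                    "sample_id": f"{ws}_{tag}",
                    "station": st,
                    "depth_layer": dp,
                    "fraction": frac,
                    "replicate": int(rep),
                    "rna_yield_per_liter": float(rng.uniform(lo, hi)),
                    "volume_filtered_liters": float(rng.uniform(20, 60)),
                }
            )
    meta = pd.DataFrame(meta_rows)

    # ---- unigene sequences and ground-truth labels --------------------
    ids, weights = _source_weights(panel)
    sources = rng.choice(len(ids), size=config.n_unigenes, p=weights)
    n_trunc = int(round(config.truncated_fraction * config.n_unigenes))
    trunc_set = set(
        rng.choice(config.n_unigenes, size=n_trunc, replace=False).tolist()
    )
    aa_seqs: dict[str, str] = {}
    nt_seqs: dict[str, str] = {}
    truth_rows = []
    for i, src in enumerate(sources):
        uid = f"UG{i + 1:06d}"
        ref = panel[ids[src]]
        seq, truth = mutate_reference(ref, config.divergence_pct, rng=rng)
        truncated = i in trunc_set
        if truncated:
            seq = _truncate(seq, ref.helix_cf_span, rng)
        aa_seqs[uid] = seq
        nt_seqs[uid] = back_translate(seq)
        truth.update(unigene_id=uid, truncated=truncated)
        truth_rows.append(truth)
    truth_df = pd.DataFrame(truth_rows).set_index("unigene_id", drop=False)

    # ---- latent nutrient gradient (one value per water sample;
    # replicate casts are treated as independent water parcels) ----------
    gradient = pd.Series(
        rng.standard_normal(len(water_samples)), index=water_samples, name="g"
    )

    # ---- raw abundance structure --------------------------------------
    n = config.n_unigenes
    base = rng.lognormal(
        config.tpm_lognormal_mu, config.tpm_lognormal_sigma, size=n
    )
    domains = truth_df["domain"].to_numpy()
    spectral = truth_df["spectral_class"].to_numpy()
    euk_mask = domains == "eukaryote"
    # half the eukaryote unigenes respond positively to the gradient, half
    # negatively: composition, not just totals, tracks the gradient
    tilt_sign = np.zeros(n)
    euk_idx = np.nonzero(euk_mask)[0]
    tilt_sign[euk_idx[::2]] = 1.0
    tilt_sign[euk_idx[1::2]] = -1.0

    trend_dir = np.zeros(n)
    for cls, direction in config.depth_trend.items():
        sign = {"increasing": 1.0, "decreasing": -1.0}[direction]
        trend_dir[spectral == cls] = sign

    frac_affinity = {  # realism: free-living bacteria small, protists large
        ("prokaryote", "small"): 2.0,
        ("prokaryote", "large"): 0.7,
        ("eukaryote", "small"): 0.3,
        ("eukaryote", "large"): 2.0,
        ("virus", "small"): 1.0,
        ("virus", "large"): 1.0,
    }

    yields = meta.set_index("sample_id")["rna_yield_per_liter"]
    shares = dict(config.planted_shares)
    dom_list = sorted(set(domains))
    unknown = set(shares) - set(dom_list)
    if set(dom_list) - set(shares):
        raise ValueError(
            f"planted_shares must cover domains {dom_list}, got {sorted(shares)}"
        )
    if unknown:
        shares = {d: shares[d] for d in dom_list}
        total = sum(shares.values())
        shares = {d: v / total for d, v in shares.items()}

    def _fraction_share_targets(ws: str) -> dict[str, dict[str, float]]:
        """Per-fraction domain shares consistent with the merged target.

        With only prokaryote/eukaryote present, the eukaryote share is
        skewed toward the large fraction as far as the drawn RNA yields
        allow while keeping the yield-weighted mean exactly at the planted
        merged share; otherwise shares are equal in both fractions (the
        weighted mean of equal shares is exact regardless of yields).
        """
        r_s = float(yields[f"{ws}_S"])
        r_l = float(yields[f"{ws}_L"])
        if set(shares) == {"prokaryote", "eukaryote"} and shares["eukaryote"] > 0:
            se = shares["eukaryote"]
            b = min(0.85, 0.8 * se * (r_s + r_l) / r_l)  # eukaryote share, large
            a = (se * (r_s + r_l) - b * r_l) / r_s  # eukaryote share, small
            if not 0.0 <= a <= 1.0:  # drawn yields make the skew infeasible
                a = b = se
            return {
                "small": {"eukaryote": a, "prokaryote": 1.0 - a},
                "large": {"eukaryote": b, "prokaryote": 1.0 - b},
            }
        return {"small": dict(shares), "large": dict(shares)}

    def _build_fraction_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
        tables: dict[str, pd.DataFrame] = {}
        for frac, tag in (("small", "S"), ("large", "L")):
            cols = {}
            affinity = np.array(
                [frac_affinity[(d, frac)] for d in domains]
            )
            for ws in water_samples:
                noise = rng.lognormal(0.0, config.sample_noise_sigma, size=n)
                g = gradient[ws]
                vals = (
                    base
                    * affinity
                    * noise
                    * np.exp(config.env_tilt * g * tilt_sign)
                    * config.depth_trend_fold ** (trend_dir * depth_index[ws])
                )
                # rescale domain groups to the per-fraction share targets
                targets = _fraction_share_targets(ws)[frac]
                out = vals.copy()
                for d, s in targets.items():
                    mask = domains == d
                    dsum = vals[mask].sum()
                    if dsum > 0:
                        out[mask] = vals[mask] * (s / dsum)
                if config.share_mode == "noisy":
                    out = out * rng.lognormal(0.0, config.share_noise_sigma, n)
                cols[f"{ws}_{tag}"] = out / out.sum() * 1e6
            tables[frac] = pd.DataFrame(cols, index=truth_df.index.rename(None))
        return tables["small"], tables["large"]

    tpm_small, tpm_large = _build_fraction_tables()

    # ---- ground-truth group sums, pre- and post-merge -----------------
    frac_rows = []
    for sample_id in list(tpm_small.columns) + list(tpm_large.columns):
        table = tpm_small if sample_id.endswith("_S") else tpm_large
        sums = table[sample_id].groupby(truth_df["domain"].values).sum()
        for d, v in sums.items():
            frac_rows.append({"sample_id": sample_id, "domain": d, "tpm_sum": v})
    frac_sums = pd.DataFrame(frac_rows)

    merged_rows = {}
    for ws in water_samples:
        r_s, r_l = float(yields[f"{ws}_S"]), float(yields[f"{ws}_L"])
        s_small = tpm_small[f"{ws}_S"].groupby(truth_df["domain"].values).sum()
        s_large = tpm_large[f"{ws}_L"].groupby(truth_df["domain"].values).sum()
        merged_rows[ws] = {
            d: merge_fractions(s_small.get(d, 0.0), s_large.get(d, 0.0), r_s, r_l)
            for d in dom_list
        }
    merged_sums = pd.DataFrame.from_dict(merged_rows, orient="index")[dom_list]

    if config.share_mode == "exact":
        realized = merged_sums.div(merged_sums.sum(axis=1), axis=0)
        for d in dom_list:
            if abs(realized[d] - shares[d]).max() > 1e-6:
                raise AssertionError(
                    "internal share planting failed; this is a bug"
                )

    # ---- merged per-unigene matrix (water samples x unigenes) ---------
    merged_unigene = {}
    for ws in water_samples:
        r_s, r_l = float(yields[f"{ws}_S"]), float(yields[f"{ws}_L"])
        merged_unigene[ws] = merge_fractions(
            tpm_small[f"{ws}_S"].to_numpy(),
            tpm_large[f"{ws}_L"].to_numpy(),
            r_s,
            r_l,
        )
    merged_unigene = pd.DataFrame.from_dict(
        merged_unigene, orient="index", columns=truth_df.index.rename(None)
    )

    # ---- environmental table (gradient-coupled nutrients) -------------
    # Nutrients are coupled to the *realized* eukaryotic PPR community
    # gradient -- the standardized first principal coordinate of the
    # Bray-Curtis matrix over merged eukaryotic PPR profiles -- so the
    # planted association lives on the distance-matrix scale that a Mantel
    # test estimates.  env_effect_r is that distance-level association: the
    # latent mixing weight is solved per realization so that the correlation
    # between the community distance triangle and the z-scored Euclidean
    # nutrient distance triangle equals it.  Nutrients are log-linear in the
    # latent (log-normal given the axis); the TPM tables are never touched.
    rho = config.env_effect_r
    euk_ppr = truth_df.index[
        (truth_df["domain"] == "eukaryote") & truth_df["is_ppr"]
    ]
    if len(euk_ppr) >= 2 and rho > 0:
        euk_bc = _bray_curtis(merged_unigene[list(euk_ppr)].to_numpy())
        sig = pd.Series(_pcoa_axis1(euk_bc), index=water_samples)
    else:
        euk_bc = None
        sig = gradient.copy()
    u_scores = np.asarray((sig - sig.mean()) / max(sig.std(ddof=1), 1e-12))
    nut_params = {  # (scale umol/L, log-sd): surface-ocean magnitudes
        "no2": (0.05, 0.5),
        "po4": (0.04, 0.6),
        "no3_no2": (0.4, 0.8),
        "sio3": (2.0, 0.5),
    }
    nut_names = tuple(nut_params)
    log_sds = np.array([nut_params[v][1] for v in nut_names])
    eps = rng.standard_normal((len(water_samples), len(nut_names)))
    if euk_bc is not None:
        weight = _calibrate_mixing_weight(rho, euk_bc, u_scores, eps, log_sds)
    else:
        weight = 0.0
    nut_latent = weight * u_scores[:, None] + np.sqrt(1 - weight**2) * eps

    station_depth_m = {
        ("C6", "SUR"): 5.0, ("C6", "DCM"): 30.0, ("C6", "BOT"): 60.0,
        ("C9", "SUR"): 5.0, ("C9", "DCM"): 50.0, ("C9", "BOT"): 90.0,
    }
    env_rows = {}
    for k, ws in enumerate(water_samples):
        st, dp, _ = ws.split("_")
        row = {}
        for v, var in enumerate(nut_names):
            scale, sd = nut_params[var]
            row[var] = scale * np.exp(sd * nut_latent[k, v])
        depth_m = station_depth_m.get((st, dp), 10.0) * (
            1 + 0.02 * rng.standard_normal()
        )
        row["depth_m"] = depth_m
        row["temperature_c"] = 29.0 - 0.12 * depth_m + 0.2 * rng.standard_normal()
        row["salinity"] = 33.5 + 0.005 * depth_m + 0.05 * rng.standard_normal()
        row["np_ratio"] = row["no3_no2"] / row["po4"]
        env_rows[ws] = row
    env = pd.DataFrame.from_dict(env_rows, orient="index")

    # ---- taxon relative abundances coupled to PPR expression ----------
    taxa = sorted(
        {t for t in truth_df.loc[truth_df["is_ppr"], "taxon"] if t}
    )
    r_ab = config.abundance_effect_r
    abund = {}
    for taxon in taxa:
        members = truth_df.index[
            (truth_df["taxon"] == taxon) & truth_df["is_ppr"]
        ]
        expr = merged_unigene[members].sum(axis=1)
        if expr.std(ddof=0) == 0:
            latent = np.zeros(len(expr))
        else:
            latent = (expr - expr.mean()) / expr.std(ddof=0)
        noise = rng.standard_normal(len(expr))
        signal = r_ab * latent + np.sqrt(1 - r_ab**2) * noise
        abund[taxon] = np.maximum(signal - signal.min() + 0.05, 0.0)
    abund["Other"] = np.full(len(water_samples), 2.0)
    abund_df = pd.DataFrame(abund, index=water_samples)
    abund_df = abund_df.div(abund_df.sum(axis=1), axis=0)

    truth = GroundTruth(
        unigenes=truth_df.reset_index(drop=True),
        merged_group_sums=merged_sums,
        fraction_group_sums=frac_sums,
        gradient=gradient,
        env_coefficients={
            "env_effect_r": rho,
            "env_tilt": config.env_tilt,
            "abundance_effect_r": r_ab,
            "nutrient_params": nut_params,
            "copula_weight": weight,
            "euk_signal": sig.to_dict(),
        },
    )
    return SyntheticCommunity(
        config=config,
        aa_seqs=aa_seqs,
        nt_seqs=nt_seqs,
        tpm_small=tpm_small,
        tpm_large=tpm_large,
        sample_meta=meta,
        env=env,
        taxon_abundance=abund_df,
        ground_truth=truth,
    )
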