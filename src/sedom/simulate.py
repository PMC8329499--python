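"""Ground-truth-labeled synthetic studies of stratified sediment DOM.

The generator emulates the sampling design this pipeline targets: one
sediment core sectioned at 5-cm intervals down to 100 cm and 10-cm intervals
below (40 depths by default), several thousand CHONS formulas between 200 and
800 Da whose composition shifts with depth (rising DBE and aromaticity,
falling H/C), per-sample FT-ICR MS peak lists with configurable mass error
and signal-to-noise structure, and an ASV table in which designated microbial
guilds are coupled to designated molecule sets at a target Pearson
correlation (archaeal guilds to high-DBE molecules, bacterial guilds to
low-DBE molecules by default).

Every planted effect is recorded in a :class:`GroundTruth` object so that
each pipeline stage can be scored against what was actually simulated. All
stages are deterministic functions of the configuration: stage k draws from
``numpy.random.default_rng([seed, k])``, so the same config reproduces every
table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .formula import FormulaComposition, ion_mz
from .indices import index_table

__all__ = [
    "CouplingSpec",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticStudy",
    "simulate_formula_library",
    "simulate_depth_profiles",
    "simulate_peaklists",
    "simulate_asv_table",
    "simulate_study",
    "write_study",
]

_ARCHAEAL_CLASSES = ("Bathyarchaeia", "Lokiarchaeia", "MBG-D", "Thermoplasmata")
_BACTERIAL_CLASSES = (
    "Gammaproteobacteria",
    "Alphaproteobacteria",
    "Dehalococcoidia",
    "Anaerolineae",
    "Desulfobacterales",
    "Desulfobulbia",
    "Desulfatiglandales",
    "Planctomycetota",
)


@dataclass(frozen=True)
class CouplingSpec:
    """A microbial guild coupled to a molecule set at a target correlation.

    The guild's molecules share one latent trajectory (optionally loaded on
    depth via ``depth_loading``); the guild's ASVs track the realized mean
    profile of that molecule set, with independent noise calibrated so the
    ASV-molecule Pearson correlation hits ``target_r``. Every ASV x molecule
    combination within the guild is a planted association (n_asvs x
    n_molecules pairs).
    """

    name: str
    domain: str  # "Bacteria" | "Archaea"
    n_asvs: int
    n_molecules: int
    molecule_rule: str  # "dbe_high" (11 <= DBE <= 18) | "dbe_low" (DBE < 10)
    target_r: float = 0.9
    depth_loading: float = 0.0  # correlation of the guild latent with depth


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and effect sizes for one synthetic core.

    Defaults mirror the target design: 20 upper depths (5-100 cm, 5-cm step),
    20 deep depths (110-300 cm, 10-cm step), 5,000 formulas drawn with
    heteroatom-family proportions CHO/CHON/CHOS/CHONS = 58.1/28.2/11.1/2.6%,
    1,000 ASVs of which 87 form four coupled guilds, 0.3 ppm mass error.
    """

    seed: int
    upper_range: tuple[int, int, int] = (5, 100, 5)  # (first, last, step) in cm
    deep_range: tuple[int, int, int] = (110, 300, 10)
    n_formulas: int = 5000
    n_asvs: int = 1000
    family_proportions: tuple[tuple[str, float], ...] = (
        ("CHO", 0.581),
        ("CHON", 0.282),
        ("CHOS", 0.111),
        ("CHONS", 0.026),
    )
    mass_range: tuple[float, float] = (200.0, 800.0)
    depth_effect: float = 1.0  # scale of the per-molecule exponential depth trend
    n_differential: int = 100  # molecules given a step shift between strata
    differential_fold: float = 4.0
    n_unique_upper: int = 50  # molecules detected only in one stratum
    n_unique_deep: int = 50
    intensity_sigma: float = 0.5  # lognormal multiplicative noise (log-sd)
    detection_quantile: float = 0.2  # per-sample intensity censoring (detection limit)
    library_size: int = 50_000  # 16S reads per sample (Poisson detection)
    mass_error_ppm: float = 0.3
    noise_peak_rate: float = 0.05  # noise peaks per detected molecule
    sn_below4_frac: float = 0.05  # fraction of true peaks planted below s/n 4
    archaea_fraction: float = 0.25
    coupled_intensity_boost: float = 10.0  # base intensity of guild target molecules
    guild_molecule_cor: float = 0.94  # shared-factor correlation within a guild's molecules
    guild_molecule_cv: float = 0.3  # coefficient of variation of guild molecules
    #: two broad guilds carry the domain-level DBE contrast; two small tight
    #: guilds plant near-square bicliques, the kind of dense pocket MCODE can
    #: recover from a bipartite correlation network
    couplings: tuple[CouplingSpec, ...] = (
        CouplingSpec("bacteria_lowDBE", "Bacteria", 40, 25, "dbe_low", 0.9, -0.4),
        CouplingSpec("archaea_highDBE", "Archaea", 40, 25, "dbe_high", 0.9, 0.4),
        CouplingSpec("bacteria_module", "Bacteria", 4, 4, "dbe_low", 0.95, -0.4),
        CouplingSpec("archaea_module", "Archaea", 3, 3, "dbe_high", 0.95, 0.4),
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_formulas", "n_asvs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if sum(s.n_asvs for s in self.couplings) > self.n_asvs:
            raise ValueError("more guild ASVs than n_asvs")
        if sum(s.n_molecules for s in self.couplings) > self.n_formulas:
            raise ValueError("more guild molecules than n_formulas")

    @property
    def depths(self) -> np.ndarray:
        u = np.arange(self.upper_range[0], self.upper_range[1] + 1, self.upper_range[2])
        d = np.arange(self.deep_range[0], self.deep_range[1] + 1, self.deep_range[2])
        return np.concatenate([u, d])

    @property
    def n_samples(self) -> int:
        return len(self.depths)

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{d:03d}" for d in self.depths]

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["couplings"] = [asdict(c) for c in self.couplings]
        data["family_proportions"] = [list(t) for t in self.family_proportions]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["couplings"] = tuple(CouplingSpec(**c) for c in raw.get("couplings", ()))
        raw["family_proportions"] = tuple(
            (str(k), float(v)) for k, v in raw.get("family_proportions", ())
        )
        for key in ("upper_range", "deep_range", "mass_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


# ---------------------------------------------------------------------------
# formula library


def _draw_formula(family: str, rng: np.random.Generator) -> FormulaComposition | None:
    c = int(rng.integers(8, 41))
    hc = float(np.clip(rng.normal(1.25, 0.35), 0.4, 2.3))
    oc = float(np.clip(rng.normal(0.45, 0.18), 0.02, 1.15))
    h = max(int(round(c * hc)), 4)
    o = int(round(c * oc))
    n = int(rng.choice([1, 2], p=[0.8, 0.2])) if "N" in family else 0
    s = 1 if "S" in family else 0
    if (h - n) % 2:  # integer DBE for the neutral molecule
        h += 1 if h < 2 * c + n else -1
    if h < 4 or not (0.3 <= h / c <= 2.5) or o / c > 1.2:
        return None
    dbe = 1 + (2 * c - h + n) / 2
    if dbe < 0 or not (-10 <= dbe - o <= 10):  # DBE-O plausibility window
        return None
    return FormulaComposition(c=c, h=h, n=n, o=o, s=s, p=0)


def simulate_formula_library(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Draw the molecule universe.

    Returns ``(indices, base_intensity)``: an index table (one row per unique
    formula, see :func:`sedom.indices.index_table`) and lognormal base
    intensities indexed the same way. Family counts are one multinomial draw
    from the configured proportions; compositions are rejection-sampled from
    the element grid under the standard plausibility rules and the mass range.
    """
    rng = _rng(cfg, 0)
    fams = [f for f, _ in cfg.family_proportions]
    probs = np.array([p for _, p in cfg.family_proportions], dtype=float)
    probs = probs / probs.sum()
    counts = rng.multinomial(cfg.n_formulas, probs)
    from .formula import neutral_mass  # local import to avoid cycle at module load

    seen: dict[str, FormulaComposition] = {}
    for fam, want in zip(fams, counts):
        got = 0
        attempts = 0
        while got < want:
            attempts += 1
            if attempts > 2000 * max(want, 1):
                raise RuntimeError(f"infeasible constraints: cannot draw {want} {fam} formulas")
            comp = _draw_formula(fam, rng)
            if comp is None:
                continue
            m = neutral_mass(comp)
            if not (cfg.mass_range[0] <= m <= cfg.mass_range[1]):
                continue
            key = comp.hill()
            if key in seen:
                continue
            seen[key] = comp
            got += 1
    indices = index_table(seen.values())
    base = pd.Series(rng.lognormal(0.0, 1.0, size=len(indices)), index=indices.index, name="base")
    return indices, base


# ---------------------------------------------------------------------------
# planted design


@dataclass(frozen=True)
class _Design:
    betas: pd.Series  # per-molecule exponential depth-trend coefficient
    differential_upper: tuple[str, ...]
    differential_deep: tuple[str, ...]
    unique_upper: tuple[str, ...]
    unique_deep: tuple[str, ...]
    couplings: pd.DataFrame  # columns asv, molecule, domain, guild, target_r


def _design(cfg: SimulationConfig, indices: pd.DataFrame, base: pd.Series) -> _Design:
    rng = _rng(cfg, 1)
    molecules = np.array(indices.index)
    dbe = indices["dbe"].to_numpy(dtype=float)
    hc = indices["hc"].to_numpy(dtype=float)

    def z(x):
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    # recalcitrant (high-DBE, low-H/C) molecules are enriched downcore
    score = np.clip((z(dbe) - z(hc)) / 2.0, -2.0, 2.0)
    betas = pd.Series(cfg.depth_effect * 0.4 * score, index=indices.index, name="beta")

    pool = list(molecules)
    rng.shuffle(pool)
    k = cfg.n_differential
    if k + cfg.n_unique_upper + cfg.n_unique_deep > len(pool):
        raise ValueError("not enough molecules for the planted design")
    # differential shifts are planted on molecules above the median base
    # intensity: a fold change on a molecule sitting under the detection
    # limit is unobservable by construction and would not be ground truth
    median_base = float(base.median())
    abundant = [m for m in pool if base[m] >= median_base]
    if k > len(abundant):
        raise ValueError("not enough detectable molecules for the differential design")
    diff = abundant[:k]
    diff_upper = tuple(sorted(diff[: k // 2]))
    diff_deep = tuple(sorted(diff[k // 2 :]))
    rest = [m for m in pool if m not in set(diff)]
    uniq_upper = tuple(sorted(rest[: cfg.n_unique_upper]))
    uniq_deep = tuple(sorted(rest[cfg.n_unique_upper : cfg.n_unique_upper + cfg.n_unique_deep]))
    reserved = set(diff) | set(uniq_upper) | set(uniq_deep)

    rows = []
    asv_counter = 0
    taken: set[str] = set()
    for spec in cfg.couplings:
        if spec.molecule_rule == "dbe_high":
            ok = (indices["dbe"] >= 11) & (indices["dbe"] <= 18)
        elif spec.molecule_rule == "dbe_low":
            ok = indices["dbe"] < 10
        else:
            raise ValueError(f"unknown molecule_rule {spec.molecule_rule!r}")
        eligible = [m for m in indices.index[ok] if m not in reserved and m not in taken]
        if len(eligible) < spec.n_molecules:
            raise ValueError(
                f"coupling {spec.name!r}: only {len(eligible)} eligible molecules "
                f"for {spec.n_molecules} requested"
            )
        chosen = list(rng.choice(eligible, size=spec.n_molecules, replace=False))
        taken.update(chosen)
        asvs = [f"ASV{asv_counter + i + 1:04d}" for i in range(spec.n_asvs)]
        asv_counter += spec.n_asvs
        for a in asvs:
            for m in chosen:
                rows.append(
                    {
                        "asv": a,
                        "molecule": m,
                        "domain": spec.domain,
                        "guild": spec.name,
                        "target_r": spec.target_r,
                    }
                )
    couplings = pd.DataFrame(rows, columns=["asv", "molecule", "domain", "guild", "target_r"])
    return _Design(betas, diff_upper, diff_deep, uniq_upper, uniq_deep, couplings)


# ---------------------------------------------------------------------------
# depth profiles


def simulate_depth_profiles(
    indices: pd.DataFrame, base: pd.Series, cfg: SimulationConfig
) -> tuple[pd.DataFrame, _Design]:
    """Molecule x sample relative-abundance matrix with planted structure.

    Background molecules: per-depth intensity = base x exp(beta x depth) x
    stratum fold-changes x lognormal noise, censored below a per-sample
    detection limit (the ``detection_quantile`` of that sample's intensities,
    emulating the instrument's s/n floor). Guild molecules are abundant
    compounds (base = ``coupled_intensity_boost``) whose relative variation
    shares a latent guild factor, optionally loaded on depth. Columns are
    closed to fractions. Returns the matrix and the planted design.
    """
    design = _design(cfg, indices, base)
    rng = _rng(cfg, 2)
    depths = cfg.depths.astype(float)
    zdepth = (depths - depths.mean()) / (np.ptp(depths) / 2.0 or 1.0)
    zdepth_sd = zdepth / (zdepth.std() or 1.0)
    deep = depths >= cfg.deep_range[0]
    beta = design.betas.to_numpy()[:, None]
    base_arr = base.to_numpy(dtype=float)
    log_int = np.log(np.maximum(base_arr[:, None], 1e-300)) + beta * zdepth[None, :]
    raw = np.exp(log_int)
    fold = np.log(cfg.differential_fold)
    for mols, stratum in ((design.differential_upper, ~deep), (design.differential_deep, deep)):
        pos = indices.index.get_indexer(list(mols))
        raw[np.ix_(pos, np.nonzero(stratum)[0])] *= np.exp(fold)
    raw *= rng.lognormal(0.0, cfg.intensity_sigma, size=raw.shape)
    # guild molecules: stable abundant baseline + correlated relative variation
    a = np.sqrt(cfg.guild_molecule_cor)
    for spec in cfg.couplings:
        mols = design.couplings.loc[design.couplings["guild"] == spec.name, "molecule"].unique()
        if not len(mols):
            continue
        w = float(np.clip(spec.depth_loading, -1.0, 1.0))
        latent = w * zdepth_sd + np.sqrt(1.0 - w**2) * rng.standard_normal(len(depths))
        pos = indices.index.get_indexer(list(mols))
        eps = rng.standard_normal((len(pos), len(depths)))
        rel = 1.0 + cfg.guild_molecule_cv * (a * latent[None, :] + np.sqrt(1 - a**2) * eps)
        raw[pos] = cfg.coupled_intensity_boost * np.maximum(rel, 0.05)
    if cfg.detection_quantile > 0:
        # per-sample detection limit; guild molecules sit far above it
        thresh = np.quantile(raw, cfg.detection_quantile, axis=0, keepdims=True)
        raw = np.where(raw < thresh, 0.0, raw)
    for mols, stratum in ((design.unique_upper, deep), (design.unique_deep, ~deep)):
        pos = indices.index.get_indexer(list(mols))
        raw[np.ix_(pos, np.nonzero(stratum)[0])] = 0.0
        # guarantee detection somewhere inside the home stratum
        home = np.nonzero(~stratum)[0]
        for i in pos:
            if raw[i, home].sum() == 0:
                raw[i, home[0]] = base.iloc[i]
    totals = raw.sum(axis=0)
    if (totals <= 0).any():
        raise RuntimeError("a sample lost all intensity; lower detection_quantile")
    fractions = raw / totals
    return (
        pd.DataFrame(fractions, index=indices.index, columns=cfg.sample_ids),
        design,
    )


# ---------------------------------------------------------------------------
# peak lists


def simulate_peaklists(
    profiles: pd.DataFrame, cfg: SimulationConfig
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-sample peak lists (mz, intensity, sn) with a peak-to-formula map.

    Detected molecules appear at their [M-H]- m/z plus Gaussian relative
    error of ``mass_error_ppm``; a configurable fraction of true peaks is
    planted below the s/n threshold of 4, and uniform-random noise peaks are
    added at ``noise_peak_rate`` per detected molecule (truth label "noise").
    """
    from .formula import parse_formula

    rng = _rng(cfg, 3)
    mz_true = np.array([ion_mz(parse_formula(f)) for f in profiles.index])
    peaklists: dict[str, pd.DataFrame] = {}
    truth_rows = []
    for sample in profiles.columns:
        frac = profiles[sample].to_numpy()
        det = np.nonzero(frac > 0)[0]
        err = rng.normal(0.0, cfg.mass_error_ppm, size=len(det)) * 1e-6
        mz = mz_true[det] * (1.0 + err)
        intensity = frac[det] * 1e10
        low = rng.random(len(det)) < cfg.sn_below4_frac
        sn = 4.5 + rng.lognormal(2.5, 0.8, size=len(det))
        sn[low] = rng.uniform(0.5, 4.0, size=int(low.sum()))
        formulas = profiles.index.to_numpy()[det]
        n_noise = int(round(cfg.noise_peak_rate * len(det)))
        if n_noise:
            mz_noise = rng.uniform(cfg.mass_range[0], cfg.mass_range[1], size=n_noise)
            mz = np.concatenate([mz, mz_noise])
            intensity = np.concatenate([intensity, rng.lognormal(np.log(np.median(intensity) if len(intensity) else 1.0), 1.0, size=n_noise)])
            sn = np.concatenate([sn, 4.5 + rng.lognormal(1.5, 0.8, size=n_noise)])
            formulas = np.concatenate([formulas, np.array(["noise"] * n_noise)])
        order = np.argsort(mz)
        df = pd.DataFrame({"mz": mz[order], "intensity": intensity[order], "sn": sn[order]})
        peaklists[sample] = df
        truth_rows.append(
            pd.DataFrame({"sample": sample, "mz": mz[order], "formula": formulas[order]})
        )
    truth = pd.concat(truth_rows, ignore_index=True)
    return peaklists, truth


# ---------------------------------------------------------------------------
# ASV table


def simulate_asv_table(
    cfg: SimulationConfig,
    profiles: pd.DataFrame,
    indices: pd.DataFrame,
    base: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """ASV x sample relative abundances, taxonomy, and the coupling table.

    Guild ASVs track the realized mean profile of the guild's molecule set,
    with independent noise calibrated so the expected ASV-molecule Pearson
    correlation equals the guild's target (tau from the attenuation identity
    r = c / sqrt(1 + tau^2), c being the realized molecule-to-mean
    correlation); background ASVs are unstructured lognormal noise. Latent
    abundances are closed to one per sample and observed through Poisson
    sequencing at ``library_size`` reads, so rare ASVs drop out the way they
    do in real amplicon data; the returned table holds the resulting relative
    abundances.
    """
    design = _design(cfg, indices, base)
    rng = _rng(cfg, 4)
    n = profiles.shape[1]
    abund = np.zeros((cfg.n_asvs, n))
    asv_ids = [f"ASV{i + 1:04d}" for i in range(cfg.n_asvs)]
    n_coupled = sum(spec.n_asvs for spec in cfg.couplings)
    tax_rows: list[dict] = [{}] * n_coupled
    # background first, so the sequencing-noise compensation below can use
    # the realized community total
    for i in range(n_coupled, cfg.n_asvs):
        base = rng.lognormal(0.0, 1.0)
        abund[i] = base * rng.lognormal(0.0, 0.7, size=n)
        domain = "Archaea" if rng.random() < cfg.archaea_fraction else "Bacteria"
        classes = _ARCHAEAL_CLASSES if domain == "Archaea" else _BACTERIAL_CLASSES
        tax_rows.append(
            {"asv": asv_ids[i], "domain": domain, "class": str(rng.choice(classes)), "guild": ""}
        )
    total = float(abund[n_coupled:].sum(axis=0).mean()) + 3.0 * n_coupled
    row = 0
    guild_rows: list[tuple[CouplingSpec, np.ndarray, np.ndarray, float, slice]] = []
    for spec in cfg.couplings:
        guild = design.couplings[design.couplings["guild"] == spec.name]
        mols = guild["molecule"].unique()
        asvs = guild["asv"].unique()
        sub = profiles.loc[mols].to_numpy(dtype=float)
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        zmols = (sub - sub.mean(axis=1, keepdims=True)) / sd
        mean_profile = zmols.mean(axis=0)
        msd = mean_profile.std()
        z = mean_profile / msd if msd > 0 else rng.standard_normal(n)
        cbar = float(np.mean([np.corrcoef(z, m)[0, 1] for m in zmols]))
        block = slice(row, row + len(asvs))
        guild_rows.append((spec, z, sub, cbar, block))
        for a in asvs:
            classes = _ARCHAEAL_CLASSES if spec.domain == "Archaea" else _BACTERIAL_CLASSES
            tax_rows[row] = {
                "asv": a,
                "domain": spec.domain,
                "class": str(rng.choice(classes)),
                "guild": spec.name,
            }
            row += 1
    # calibrate the guild noise level so the realized ASV-molecule Pearson
    # correlation lands on target despite three attenuations: the
    # molecule-to-guild-mean correlation (cbar), Poisson counting noise at the
    # expected read depth (gamma = sqrt(V/(V + lambda)), V = (L/T)^2 (1+tau^2)),
    # and compositional closure (measured empirically and compensated over a
    # few refinement rounds)
    scale = cfg.library_size / total
    lam = 3.0 * scale
    t_eff = {spec.name: spec.target_r for spec, *_ in guild_rows}
    taus = {spec.name: 0.0 for spec, *_ in guild_rows}

    def _gamma(tau: float) -> float:
        v = scale**2 * (1.0 + tau**2)
        return float(np.sqrt(v / (v + lam)))

    for _ in range(3):
        for spec, z, _sub, cbar, block in guild_rows:
            tau = taus[spec.name]
            for _ in range(5):
                tau = np.sqrt(max((cbar * _gamma(tau) / t_eff[spec.name]) ** 2 - 1.0, 0.0))
            taus[spec.name] = tau
            n_g = block.stop - block.start
            abund[block] = np.clip(
                3.0 + z[None, :] + tau * rng.standard_normal((n_g, n)), 0.0, None
            )
        closed = abund / abund.sum(axis=0)
        for spec, z, sub, cbar, block in guild_rows:
            step_a = max((block.stop - block.start) // 8, 1)
            step_m = max(sub.shape[0] // 8, 1)
            rs = [
                np.corrcoef(closed[i], sub[j])[0, 1]
                for i in range(block.start, block.stop, step_a)
                for j in range(0, sub.shape[0], step_m)
            ]
            realized = float(np.median(rs))
            if realized > 0:
                # realized lacks the Poisson stage, which gamma accounts for
                predicted = realized * _gamma(taus[spec.name])
                t_eff[spec.name] = min(t_eff[spec.name] * spec.target_r / predicted, 0.999)
    latent = abund / abund.sum(axis=0)
    counts = rng.poisson(latent * cfg.library_size)
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise RuntimeError("a sample has no ASV reads; raise library_size")
    table = pd.DataFrame(counts / totals, index=asv_ids, columns=profiles.columns)
    taxonomy = pd.DataFrame(tax_rows).set_index("asv").loc[asv_ids]
    return table, taxonomy, design.couplings


# ---------------------------------------------------------------------------
# whole-study orchestration


@dataclass(frozen=True)
class GroundTruth:
    betas: pd.Series
    differential_upper: tuple[str, ...]
    differential_deep: tuple[str, ...]
    unique_upper: tuple[str, ...]
    unique_deep: tuple[str, ...]
    couplings: pd.DataFrame
    peak_map: pd.DataFrame | None = None

    @property
    def differential(self) -> tuple[str, ...]:
        return tuple(sorted(self.differential_upper + self.differential_deep))


@dataclass
class SyntheticStudy:
    cfg: SimulationConfig
    indices: pd.DataFrame  # per-formula index table
    dom: pd.DataFrame  # molecule x sample fractions
    asv: pd.DataFrame  # ASV x sample fractions
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame  # per-sample depth, stratum, geochemistry
    truth: GroundTruth
    peaklists: dict[str, pd.DataFrame] | None = None


def _metadata(cfg: SimulationConfig) -> pd.DataFrame:
    rng = _rng(cfg, 5)
    d = cfg.depths.astype(float)
    n = len(d)
    meta = pd.DataFrame(
        {
            "depth_cm": d,
            "stratum": np.where(d <= cfg.upper_range[1], "upper", "deep"),
            "so4": 28.0 * np.exp(-d / 80.0) + rng.normal(0, 1.0, n),
            "nh4": 50.0 * (1.0 - np.exp(-d / 120.0)) + rng.normal(0, 3.0, n),
            "dic": 2.0 + 0.02 * d + rng.normal(0, 0.5, n),
            "fe_ii": 10.0 * np.exp(-(((d - 60.0) / 50.0) ** 2)) + rng.normal(0, 0.5, n),
            "d13c_dic": -8.0 - 0.02 * d + rng.normal(0, 1.0, n),
            "d13c_toc": -24.0 + rng.normal(0, 0.3, n),
        },
        index=cfg.sample_ids,
    )
    meta.index.name = "sample"
    return meta


def simulate_study(cfg: SimulationConfig, with_peaklists: bool = False) -> SyntheticStudy:
    """Generate a complete synthetic study (all tables plus ground truth)."""
    indices, base = simulate_formula_library(cfg)
    dom, design = simulate_depth_profiles(indices, base, cfg)
    asv, taxonomy, couplings = simulate_asv_table(cfg, dom, indices, base)
    peaklists = peak_map = None
    if with_peaklists:
        peaklists, peak_map = simulate_peaklists(dom, cfg)
    truth = GroundTruth(
        betas=design.betas,
        differential_upper=design.differential_upper,
        differential_deep=design.differential_deep,
        unique_upper=design.unique_upper,
        unique_deep=design.unique_deep,
        couplings=couplings,
        peak_map=peak_map,
    )
    return SyntheticStudy(
        cfg=cfg,
        indices=indices,
        dom=dom,
        asv=asv,
        taxonomy=taxonomy,
        metadata=_metadata(cfg),
        truth=truth,
        peaklists=peaklists,
    )


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write all study tables as TSV (plus ground truth as JSON/TSV)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.dom.to_csv(out / "dom.tsv", sep="\t")
    study.asv.to_csv(out / "asv.tsv", sep="\t")
    study.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t")
    study.metadata.to_csv(out / "metadata.tsv", sep="\t")
    study.indices.to_csv(out / "formula_indices.tsv", sep="\t")
    study.cfg.to_yaml(out / "config.yaml")
    if study.peaklists:
        pk = out / "peaklists"
        pk.mkdir(exist_ok=True)
        for sample, df in study.peaklists.items():
            df.to_csv(pk / f"{sample}.tsv", sep="\t", index=False)
    truth = study.truth
    truth.couplings.to_csv(out / "groundtruth_couplings.tsv", sep="\t", index=False)
    import json

    gt = {
        "differential_upper": list(truth.differential_upper),
        "differential_deep": list(truth.differential_deep),
        "unique_upper": list(truth.unique_upper),
        "unique_deep": list(truth.unique_deep),
    }
    (out / "groundtruth.json").write_text(json.dumps(gt, indent=1))
    if truth.peak_map is not None:
        truth.peak_map.to_csv(out / "groundtruth_peaks.tsv", sep="\t", index=False)
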