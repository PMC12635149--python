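"""Hierarchical synthetic specimen generator.

Emulates the sampling design of the field study: 18 collection sites,
each hosting one of three *Crematogaster* model species and a syntopic
population of the *Camponotus lateralis* mimic; several nests per genus
per site; several workers per nest.

Every trait is generated on the analysis scale (square-rooted RGB for
color, µm for cephalic size) as

    value = archetype + site effect + nest effect + individual effect

with independent Gaussian effects at the three hierarchy levels.  The
mimic's color archetype at a site is a convex blend of a mimic baseline
toward the archetype of the *syntopic* model species,

    mimic archetype(site) = (1 - λ) · baseline + λ · model archetype,

so λ = 0 makes the site labels uninformative about mimic color (a true
null for the syntopy statistic) and λ = 1 makes the mimic converge on its
local model exactly.  Cephalic size blends analogously with its own
λ_size.  Site effects are drawn independently for model and mimic, so
syntopic convergence can come only from λ — the mimicry statistic stays
falsifiable.  Sqrt-scale values are clamped to [0, √255] before squaring
back to stored RGB.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import (
    BODY_PARTS,
    COLOR_COLUMNS,
    MODEL_TAXA,
    SiteRegistry,
    annotate,
)

SQRT_MAX = float(np.sqrt(255.0))


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


def _archetype(head, meso, petiole, gaster):
    # channel triples are sqrt-scale (R, G, B); pronotum/mesonotum/propodeum
    # share the mesosoma triple
    parts = {"he": head, "pr": meso, "me": meso, "pp": meso,
             "pe": petiole, "ga": gaster}
    return np.array(
        [parts[p][i] for p in BODY_PARTS for i in range(3)], dtype=float
    )


# Stylized sqrt-scale color archetypes. "Reddish" ≈ raw RGB (150, 59, 40),
# "blackish" ≈ (45, 35, 30), "dark brownish" ≈ (56, 40, 34).
_REDDISH = (12.2, 7.7, 6.3)
_BLACKISH = (6.7, 5.9, 5.5)
_BROWNISH = (7.5, 6.3, 5.8)


def default_archetypes() -> dict[str, dict]:
    """Stylized per-taxon archetypes for the three model species and the
    mimic baseline.

    *scutellaris*: reddish head on a blackish body; *schmidti*: reddish
    head, mesosoma and petiole, blackish gaster; *ionia*: homogeneously
    dark brownish.  The mimic baseline is the species-typical
    *Ca. lateralis* habitus — reddish head, intermediate mesosoma, dark
    gaster.  Colors are sqrt-scale channel means; ``cs`` is the cephalic
    size mean in µm.
    """
    return {
        "scutellaris": {
            "color": _archetype(_REDDISH, _BLACKISH, _BLACKISH, _BLACKISH),
            "cs": 1079.0,
        },
        "schmidti": {
            "color": _archetype(_REDDISH, _REDDISH, _REDDISH, _BLACKISH),
            "cs": 990.0,
        },
        "ionia": {
            "color": _archetype(_BROWNISH, _BROWNISH, _BROWNISH, _BROWNISH),
            "cs": 996.0,
        },
        "baseline": {
            "color": _archetype((11.0, 7.3, 6.2), (8.0, 6.3, 5.8),
                                (7.5, 6.1, 5.7), (6.5, 5.8, 5.4)),
            "cs": 1030.0,
        },
    }


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the study-like conditions.

    Color variance components are on the sqrt-channel scale, size
    components in µm.  Nest and worker counts per site echo the field
    sampling (3–6 model nests, 3–9 mimic nests, ~8 workers each).
    """

    archetypes: dict[str, dict] = field(default_factory=default_archetypes)
    lambda_color: float = 0.9
    lambda_size: float = 0.3
    sigma_site: float = 0.3
    sigma_nest: float = 0.3
    sigma_ind: float = 0.5
    sigma_site_size: float = 30.0
    sigma_nest_size: float = 30.0
    sigma_ind_size: float = 85.0
    nests_model: int = 4
    nests_mimic: int = 5
    specimens_per_nest: int = 8
    registry: SiteRegistry = field(default_factory=SiteRegistry.default)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.lambda_color <= 1.0
                and 0.0 <= self.lambda_size <= 1.0):
            raise ConfigError("lambda_color and lambda_size must be in [0, 1]")
        for name in ("sigma_site", "sigma_nest", "sigma_ind",
                     "sigma_site_size", "sigma_nest_size", "sigma_ind_size"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if min(self.nests_model, self.nests_mimic,
               self.specimens_per_nest) < 1:
            raise ConfigError("nest and specimen counts must be >= 1")
        for taxon in MODEL_TAXA + ("baseline",):
            if taxon not in self.archetypes:
                raise ConfigError(f"archetype missing for {taxon!r}")
            col = np.asarray(self.archetypes[taxon]["color"], dtype=float)
            if col.shape != (18,):
                raise ConfigError(f"{taxon}: archetype must have 18 channels")
            if np.any(col < 0) or np.any(col > SQRT_MAX):
                raise ConfigError(
                    f"{taxon}: sqrt-scale archetype outside [0, sqrt(255)]"
                )

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        """Load a flat key/value config (JSON); ``seed`` is mandatory."""
        with open(path) as fh:
            raw = json.load(fh)
        if "seed" not in raw:
            raise ConfigError("config file must set 'seed'")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in ("archetypes", "registry"):
                continue
            if f.name in raw:
                kwargs[f.name] = raw[f.name]
        cfg = cls(**kwargs)
        if "archetypes" in raw:
            arch = {
                k: {"color": np.asarray(v["color"], dtype=float),
                    "cs": float(v["cs"])}
                for k, v in raw["archetypes"].items()
            }
            cfg = dataclasses.replace(cfg, archetypes=arch)
        return cfg

    def to_file(self, path) -> None:
        raw = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name not in ("archetypes", "registry")
        }
        raw["archetypes"] = {
            k: {"color": np.asarray(v["color"]).tolist(), "cs": float(v["cs"])}
            for k, v in self.archetypes.items()
        }
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=2)


def mimic_site_archetype(config: SyntheticConfig, site_id: int):
    """Blended (color, cs) archetype of the mimic population at a site."""
    model = config.registry.model_taxon(site_id)
    lam, lam_s = config.lambda_color, config.lambda_size
    base = config.archetypes["baseline"]
    target = config.archetypes[model]
    color = (1 - lam) * np.asarray(base["color"], float) \
        + lam * np.asarray(target["color"], float)
    cs = (1 - lam_s) * base["cs"] + lam_s * target["cs"]
    return color, cs


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, dict]:
    """Draw one synthetic specimen table plus its latent truth.

    Returns ``(specimens, truth)`` where ``specimens`` is a validated,
    annotated table in the canonical schema and ``truth`` records the
    per-site/per-nest latent effects and the blended archetypes, keyed
    for parameter-recovery tests.  Fully reproducible from
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    truth: dict = {
        "config": {
            "lambda_color": config.lambda_color,
            "lambda_size": config.lambda_size,
            "sigma_site": config.sigma_site,
            "sigma_nest": config.sigma_nest,
            "sigma_ind": config.sigma_ind,
            "sigma_site_size": config.sigma_site_size,
            "sigma_nest_size": config.sigma_nest_size,
            "sigma_ind_size": config.sigma_ind_size,
            "seed": config.seed,
        },
        "site_effects": {},
        "nest_effects": {},
        "archetypes": {},
    }
    for site in config.registry.sites:
        model_taxon = config.registry.model_taxon(site)
        m_color = np.asarray(
            config.archetypes[model_taxon]["color"], float
        )
        m_cs = float(config.archetypes[model_taxon]["cs"])
        mim_color, mim_cs = mimic_site_archetype(config, site)
        for group, arch_color, arch_cs, n_nests in (
            ("model", m_color, m_cs, config.nests_model),
            ("mimic", mim_color, mim_cs, config.nests_mimic),
        ):
            # independent site effect per (site, genus, trait)
            site_eff = rng.normal(0.0, config.sigma_site, size=18)
            site_eff_cs = rng.normal(0.0, config.sigma_site_size)
            key = f"{site}:{group}"
            truth["site_effects"][key] = {
                "color": site_eff.tolist(), "cs": site_eff_cs,
            }
            truth["archetypes"][key] = {
                "color": arch_color.tolist(), "cs": arch_cs,
            }
            for nest_i in range(n_nests):
                nest_id = f"{group[:3]}{site:02d}n{nest_i + 1}"
                nest_eff = rng.normal(0.0, config.sigma_nest, size=18)
                nest_eff_cs = rng.normal(0.0, config.sigma_nest_size)
                truth["nest_effects"][f"{key}:{nest_id}"] = {
                    "color": nest_eff.tolist(), "cs": nest_eff_cs,
                }
                for spec_i in range(config.specimens_per_nest):
                    ind = rng.normal(0.0, config.sigma_ind, size=18)
                    sqrt_vals = np.clip(
                        arch_color + site_eff + nest_eff + ind,
                        0.0, SQRT_MAX,
                    )
                    rgb = sqrt_vals ** 2
                    cs = arch_cs + site_eff_cs + nest_eff_cs \
                        + rng.normal(0.0, config.sigma_ind_size)
                    cs = max(cs, 1.0)
                    # CS = (CL + CW)/2; split with a mild CL > CW shape bias
                    half_spread = abs(rng.normal(0.05, 0.02)) * cs
                    row = {
                        "site_id": site,
                        "group": group,
                        "nest_id": nest_id,
                        "specimen_id": f"{nest_id}s{spec_i + 1}",
                        "CL": cs + half_spread,
                        "CW": cs - half_spread,
                    }
                    row.update(dict(zip(COLOR_COLUMNS, rgb)))
                    rows.append(row)
    df = pd.DataFrame(rows)
    return annotate(df, config.registry), truth


def write_truth(truth: dict, path) -> None:
    """Latent-truth sidecar (JSON): archetypes and site/nest effects."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
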