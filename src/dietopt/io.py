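"""Delimited-text persistence for datasets, fronts, and run metadata.

Everything is plain UTF-8: commodity tables and group/composition/RDA tables
as CSV, run metadata and manifests as JSON.  Round-tripping a dataset through
disk reproduces it exactly at float repr precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from dietopt.optimizer import ParetoFront
from dietopt.synthetic import (
    CommodityRecord,
    CountryProfile,
    frame_to_records,
    records_to_frame,
)


def save_commodities(records: list[CommodityRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path)


def load_commodities(path: str | Path) -> list[CommodityRecord]:
    return frame_to_records(pd.read_csv(path, index_col="commodity_id"))


def save_profile(profile: CountryProfile, directory: str | Path) -> None:
    """Write a country profile as three CSV tables plus a meta JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(g, r) for g, r in sorted(profile.fbdg_groups.items())],
        columns=["group_id", "recommended_g_day"],
    ).to_csv(directory / "groups.csv", index=False)
    comp_rows = [
        (g, cid, frac)
        for g in sorted(profile.composition)
        for cid, frac in sorted(profile.composition[g].items())
    ]
    pd.DataFrame(comp_rows, columns=["group_id", "commodity_id", "fraction"]
                 ).to_csv(directory / "composition.csv", index=False)
    pd.DataFrame(
        [(n, v) for n, v in sorted(profile.rda.items())],
        columns=["nutrient", "rda"],
    ).to_csv(directory / "rda.csv", index=False)
    with open(directory / "meta.json", "w") as fh:
        json.dump(dict(country_id=profile.country_id,
                       energy_target=profile.energy_target,
                       who_protein_target=profile.who_protein_target),
                  fh, indent=2, sort_keys=True)


def load_profile(directory: str | Path) -> CountryProfile:
    directory = Path(directory)
    groups = pd.read_csv(directory / "groups.csv")
    comp = pd.read_csv(directory / "composition.csv")
    rda = pd.read_csv(directory / "rda.csv")
    with open(directory / "meta.json") as fh:
        meta = json.load(fh)
    composition: dict[str, dict[str, float]] = {}
    for _, row in comp.iterrows():
        composition.setdefault(row["group_id"], {})[row["commodity_id"]] = float(
            row["fraction"])
    return CountryProfile(
        country_id=meta["country_id"],
        fbdg_groups={r["group_id"]: float(r["recommended_g_day"])
                     for _, r in groups.iterrows()},
        composition=composition,
        rda={r["nutrient"]: float(r["rda"]) for _, r in rda.iterrows()},
        energy_target=float(meta["energy_target"]),
        who_protein_target=float(meta["who_protein_target"]),
    )


def save_front(front: ParetoFront, path: str | Path, meta: dict | None = None
               ) -> None:
    """Front as a CSV of intakes + objectives with a JSON sidecar."""
    from dietopt.reporting import front_to_frame

    path = Path(path)
    front_to_frame(front).to_csv(path, index=False)
    sidecar = dict(meta or {})
    sidecar.setdefault("n_members", len(front.members))
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, config: dict, seed: int) -> Path:
    """Record inputs hash, seed, and artifact checksums for reproducibility."""
    from dietopt import __version__

    outdir = Path(outdir)
    artifacts = sorted(
        p for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = dict(
        version=__version__,
        seed=seed,
        config_sha256=hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        artifacts={str(p.relative_to(outdir)): file_sha256(p)
                   for p in artifacts},
    )
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
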