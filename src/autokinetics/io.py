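"""Plain-text persistence: spectrum CSV+JSON sidecars, conversion CSVs,
YAML network/signature definitions, and JSON fit records."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import RateFit
from .processing import Region
from .simulate import Reaction, ReactionNetwork
from .spectra import Peak, SpectralSignature, Spectrum


def save_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    """Write x,y as two-column CSV plus a JSON sidecar with metadata."""
    path = Path(path)
    pd.DataFrame({"x": spectrum.x, "y": spectrum.y}).to_csv(path, index=False)
    sidecar = {
        "modality": spectrum.modality,
        "timestamp_min": spectrum.timestamp,
        "units": {"x": "ppm" if spectrum.modality == "nmr" else "nm", "y": "AU"},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Spectrum(
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        modality=meta["modality"],
        timestamp=float(meta["timestamp_min"]),
    )


def save_conversion_series(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, columns=["time_min", "conversion"])
    return path


def load_conversion_series(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def network_to_yaml(network: ReactionNetwork, path: str | Path) -> Path:
    doc = {
        "species": list(network.species),
        "reactions": [
            {
                "reactants": dict(r.reactants),
                "products": dict(r.products),
                "k": r.k,
                **({"orders": dict(r.orders)} if r.orders else {}),
            }
            for r in network.reactions
        ],
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def network_from_yaml(path: str | Path) -> ReactionNetwork:
    doc = yaml.safe_load(Path(path).read_text())
    return ReactionNetwork(
        species=list(doc["species"]),
        reactions=[
            Reaction(
                reactants=dict(r["reactants"]),
                products=dict(r["products"]),
                k=float(r["k"]),
                orders=dict(r.get("orders", {})),
            )
            for r in doc["reactions"]
        ],
    )


def signature_to_yaml(signature: SpectralSignature, path: str | Path) -> Path:
    doc = {
        "modality": signature.modality,
        "peaks": {
            s: [{"center": p.center, "width": p.width, "response": p.response} for p in ps]
            for s, ps in signature.peaks.items()
        },
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def signature_from_yaml(path: str | Path) -> SpectralSignature:
    doc = yaml.safe_load(Path(path).read_text())
    return SpectralSignature(
        modality=doc["modality"],
        peaks={
            s: [Peak(center=p["center"], width=p["width"], response=p["response"]) for p in ps]
            for s, ps in doc["peaks"].items()
        },
    )


def sigma_table_to_yaml(sigmas: dict[str, float], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(dict(sorted(sigmas.items()))))
    return path


def sigma_table_from_yaml(path: str | Path) -> dict[str, float]:
    return {str(k): float(v) for k, v in yaml.safe_load(Path(path).read_text()).items()}


def rate_fit_record(fit: RateFit, inputs: dict | None = None) -> str:
    """JSON record of a fit with a hash of the inputs it came from."""
    import hashlib

    payload = {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "stderr_slope": fit.stderr_slope,
        "r_squared": fit.r_squared,
        "window": list(fit.window),
    }
    if inputs is not None:
        blob = json.dumps(inputs, sort_keys=True, default=_tolist).encode()
        payload["inputs_sha256"] = hashlib.sha256(blob).hexdigest()[:16]
    return json.dumps(payload, indent=2)


def _tolist(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def region_from_dict(d: dict) -> Region:
    return Region(lo=float(d["lo"]), hi=float(d["hi"]), label=str(d["label"]))
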