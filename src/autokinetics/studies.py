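"""The three shipped reaction systems and their monitoring setups.

These are the concrete chemistries the pipeline ships configured for:

* an inverse electron-demand Diels-Alder (IEDDA) of a tetrazine with
  ethyl vinyl ether, monitored by UV-Vis on the tetrazine's visible band
  and analysed by initial rates under pseudo-first-order conditions;
* a pyridine-catalysed tosylation of substituted anilines, monitored by
  benchtop NMR on the diagnostic tosyl methyl singlets and analysed by
  initial rates, log-log orders and a Hammett regression;
* an iron(II)-imine complexation, monitored by UV-Vis on the complex's
  visible band and analysed by VTNA excess-reagent overlay.

Peak positions, widths and band responses are plausible placeholders (the
real diagnostic shifts and wavelengths are instrument- and
solvent-specific) and are fully configurable; everything downstream only
assumes resolved signals and linear response.
"""

from __future__ import annotations

import numpy as np

from .processing import ProcessingRecipe, Region
from .simulate import Reaction, ReactionNetwork
from .spectra import Peak, SpectralSignature

__all__ = [
    "IEDDA_K2",
    "IEDDA_A0_MM",
    "IEDDA_EXCESS_MM",
    "IEDDA_N_POINTS",
    "IEDDA_INTERVAL_S",
    "iedda_network",
    "iedda_signature",
    "iedda_grid",
    "iedda_recipe",
    "TOSYL_K_REF",
    "TOSYL_TSCL0_MM",
    "TOSYL_AMINE_MM",
    "TOSYL_N_POINTS",
    "TOSYL_INTERVAL_S",
    "tosylation_network",
    "tosylation_signature",
    "tosylation_grid",
    "tosylation_recipe",
    "IRON_INTERVAL_S",
    "IRON_DURATION_MIN",
    "iron_network",
    "iron_standard_mM",
    "iron_signature",
    "iron_grid",
    "iron_recipe",
]

# ---------------------------------------------------------------------------
# IEDDA: tetrazine + ethyl vinyl ether, pseudo-first-order by UV-Vis
# ---------------------------------------------------------------------------

#: Second-order rate constant used as simulation truth, mM^-1 min^-1.
IEDDA_K2 = 3.50e-5
#: Limiting tetrazine concentration, mM.
IEDDA_A0_MM = 1.5
#: Ethyl vinyl ether excess levels, mM.
IEDDA_EXCESS_MM = (100.0, 150.0, 200.0)
#: Datapoints per run and sampling interval.
IEDDA_N_POINTS = 20
IEDDA_INTERVAL_S = 82.0

#: Tetrazine visible band: center nm, HWHM nm, peak absorbance per mM.
IEDDA_BAND = Peak(center=525.0, width=25.0, response=0.2)


def iedda_network(k2: float = IEDDA_K2) -> ReactionNetwork:
    """Tz + EVE -> pyridazine product, first order in each reagent."""
    return ReactionNetwork(
        species=["Tz", "EVE", "Pz"],
        reactions=[Reaction(reactants={"Tz": 1, "EVE": 1}, products={"Pz": 1}, k=k2)],
    )


def iedda_signature() -> SpectralSignature:
    """Only the tetrazine absorbs in the visible; the adduct is colorless."""
    return SpectralSignature(modality="uvvis", peaks={"Tz": [IEDDA_BAND]})


def iedda_grid() -> np.ndarray:
    return np.arange(350.0, 701.0, 1.0)


def iedda_recipe() -> ProcessingRecipe:
    """Track [Tz] from the band maximum via its linear response factor."""
    return ProcessingRecipe(
        mode="absorbance",
        wavelength=IEDDA_BAND.center,
        calibration=IEDDA_BAND.response,
        species="Tz",
    )


# ---------------------------------------------------------------------------
# Tosylation of anilines: Hammett campaign by benchtop NMR
# ---------------------------------------------------------------------------

#: Reference (unsubstituted aniline) rate constant, mM^-order min^-1;
#: sized so the standard run reaches ~25% conversion over the 15-minute
#: monitoring window.
TOSYL_K_REF = 8.0e-4
#: Fixed tosyl chloride (limiting reagent) concentration, mM.
TOSYL_TSCL0_MM = 5.0
#: Arylamine initial concentrations, mM (highest = the standard).
TOSYL_AMINE_MM = (100.0, 75.0, 50.0, 37.5, 25.0)
#: Datapoints per run and sampling interval (15 points over 15 minutes).
TOSYL_N_POINTS = 15
TOSYL_INTERVAL_S = 60.0

#: Diagnostic tosyl methyl singlets (ppm): substrate and sulfonamide.
TOSYL_CL_PEAK = Peak(center=2.46, width=0.003, response=3.0)
TOSYL_AMIDE_PEAK = Peak(center=2.30, width=0.003, response=3.0)
TOSYL_PRODUCT_REGION = Region(lo=2.275, hi=2.325, label="tosylamide CH3")
TOSYL_SUBSTRATE_REGION = Region(lo=2.435, hi=2.485, label="TsCl CH3")


def tosylation_network(k: float = TOSYL_K_REF, amine_order: float = 0.7) -> ReactionNetwork:
    """TsCl + ArNH2 -> tosylamide with an empirical fractional amine order.

    The pyridine catalytic shuttle is not modelled; its net effect is
    lumped into the rate constant and the fractional order override.
    """
    return ReactionNetwork(
        species=["TsCl", "ArNH2", "TsNHAr"],
        reactions=[
            Reaction(
                reactants={"TsCl": 1, "ArNH2": 1},
                products={"TsNHAr": 1},
                k=k,
                orders={"ArNH2": amine_order},
            )
        ],
    )


def tosylation_signature() -> SpectralSignature:
    return SpectralSignature(
        modality="nmr",
        peaks={"TsCl": [TOSYL_CL_PEAK], "TsNHAr": [TOSYL_AMIDE_PEAK]},
    )


def tosylation_grid() -> np.ndarray:
    # 0.0005 ppm step: ~8 samples per linewidth across the methyl region
    return np.arange(2.0, 3.0, 0.0005)


def tosylation_recipe() -> ProcessingRecipe:
    """Conversion as tosylamide integral over all tosyl species combined.

    Integration is plain trapezoidal (no endpoint-chord baseline): the
    chord is anchored on two single samples, so under white noise it
    inflates the integral variance far more than it removes — it earns
    its keep only when the baseline actually drifts.  Symmetric region
    truncation cancels in the conversion ratio.
    """
    return ProcessingRecipe(
        mode="conversion",
        product_region=TOSYL_PRODUCT_REGION,
        total_regions=(TOSYL_PRODUCT_REGION, TOSYL_SUBSTRATE_REGION),
        baseline="none",
    )


# ---------------------------------------------------------------------------
# Iron(II)-imine complexation: VTNA excess screen by UV-Vis
# ---------------------------------------------------------------------------

IRON_INTERVAL_S = 112.0
IRON_DURATION_MIN = 180.0

#: The complex's visible d-d/MLCT band; reagents are assumed transparent
#: at this wavelength.
IRON_BAND = Peak(center=575.0, width=40.0, response=1.0)


def iron_network(k: float = 0.05, fp_order: float = 1.0, aq_order: float = 1.0) -> ReactionNetwork:
    """Fe + 2 AQ + 2 FP -> complex, lumped to a single empirical rate law.

    The true network (imine condensation then stepwise coordination) is
    far richer; this one-step surrogate with order overrides reproduces
    the observable excess-screen behaviour without claiming mechanism.
    """
    return ReactionNetwork(
        species=["Fe", "AQ", "FP", "FeL2"],
        reactions=[
            Reaction(
                reactants={"Fe": 1, "AQ": 2, "FP": 2},
                products={"FeL2": 1},
                k=k,
                orders={"Fe": 1.0, "AQ": aq_order, "FP": fp_order},
            )
        ],
    )


def iron_standard_mM(base: float = 1.0) -> dict[str, float]:
    """Standard stoichiometry: 1 equiv Fe, 2 equiv each ligand precursor."""
    return {"Fe": base, "AQ": 2 * base, "FP": 2 * base, "FeL2": 0.0}


def iron_signature() -> SpectralSignature:
    return SpectralSignature(modality="uvvis", peaks={"FeL2": [IRON_BAND]})


def iron_grid() -> np.ndarray:
    return np.arange(350.0, 801.0, 1.0)


def iron_recipe() -> ProcessingRecipe:
    return ProcessingRecipe(
        mode="absorbance",
        wavelength=IRON_BAND.center,
        calibration=IRON_BAND.response,
        species="FeL2",
    )
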