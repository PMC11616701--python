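"""Population presets calibrated to reference deformability-cytometry data.

Each preset is a :class:`~vdcyto.synth.PopulationSpec` whose deformability and
projected-area distributions match the reported population means/SDs for the
corresponding cell type measured in a viscoelastic deformability cytometer
(15 μm constriction channels, 0.1% w/v 1 MDa PEO carrier unless noted).
Where a quantity was not reported (Jurkat deformability SD, CLL size), the
value is a realistic choice documented in the methods note; those fields do
not enter parameter-recovery comparisons.

Velocities are nominal transit speeds in the deformation zone; for the Jurkat
pressure series they rise with driving pressure within the 0.05-2 m/s range
observed for these carrier fluids.
"""

from __future__ import annotations

from .synth import PopulationSpec

__all__ = [
    "RBC",
    "PBMC",
    "BT474",
    "MDA_MB468",
    "JURKAT_500_MBAR",
    "JURKAT_1000_MBAR",
    "JURKAT_1500_MBAR",
    "JURKAT_2000_MBAR",
    "JURKAT_PRESSURE_SERIES",
    "CLL",
    "HEALTHY_B",
    "PRESETS",
]

#: red blood cells, 20x diluted whole blood at 1 bar
RBC = PopulationSpec(
    "rbc", mean_D=0.16, sd_D=0.03, mean_area_um2=35.4, sd_area_um2=2.3,
    mean_velocity_mps=0.7,
)

#: peripheral blood mononuclear cells, same acquisition conditions as RBC
PBMC = PopulationSpec(
    "pbmc", mean_D=0.05, sd_D=0.01, mean_area_um2=28.1, sd_area_um2=4.9,
    mean_velocity_mps=0.7,
)

#: BT474 breast carcinoma line (solid invasive ductal carcinoma origin)
BT474 = PopulationSpec(
    "bt474", mean_D=0.08, sd_D=0.02, mean_area_um2=170.0, sd_area_um2=22.4,
    mean_velocity_mps=0.7,
)

#: MDA-MB468 breast cancer line (pleural effusion origin)
MDA_MB468 = PopulationSpec(
    "mda_mb468", mean_D=0.06, sd_D=0.02, mean_area_um2=103.0, sd_area_um2=16.5,
    mean_velocity_mps=0.7,
)

# Jurkat pressure series (11-μm lymphocyte line, 0.1% 1 MDa PEO): mean
# deformability rises with inlet pressure; area pi*(5.5)^2 ~ 95 μm².  The
# deformability SD (0.01) and area SD (12 μm²) are unreported and chosen to
# match the coefficient of variation of the other lymphoid populations.
_JURKAT_AREA = 95.0
_JURKAT_AREA_SD = 12.0

JURKAT_500_MBAR = PopulationSpec(
    "jurkat_500mbar", mean_D=0.030, sd_D=0.01,
    mean_area_um2=_JURKAT_AREA, sd_area_um2=_JURKAT_AREA_SD, mean_velocity_mps=0.2,
)
JURKAT_1000_MBAR = PopulationSpec(
    "jurkat_1000mbar", mean_D=0.050, sd_D=0.01,
    mean_area_um2=_JURKAT_AREA, sd_area_um2=_JURKAT_AREA_SD, mean_velocity_mps=0.4,
)
JURKAT_1500_MBAR = PopulationSpec(
    "jurkat_1500mbar", mean_D=0.065, sd_D=0.01,
    mean_area_um2=_JURKAT_AREA, sd_area_um2=_JURKAT_AREA_SD, mean_velocity_mps=0.55,
)
JURKAT_2000_MBAR = PopulationSpec(
    "jurkat_2000mbar", mean_D=0.085, sd_D=0.01,
    mean_area_um2=_JURKAT_AREA, sd_area_um2=_JURKAT_AREA_SD, mean_velocity_mps=0.7,
)

JURKAT_PRESSURE_SERIES = (
    JURKAT_500_MBAR,
    JURKAT_1000_MBAR,
    JURKAT_1500_MBAR,
    JURKAT_2000_MBAR,
)

#: chronic lymphocytic leukemia cells (patient-derived); mean D 0.09 reported,
#: SD and size chosen realistically (CLL areas exceed healthy PBMC areas)
CLL = PopulationSpec(
    "cll", mean_D=0.09, sd_D=0.02, mean_area_um2=38.0, sd_area_um2=6.0,
    mean_velocity_mps=0.7,
)

#: healthy B lymphocytes (mean D close to PBMC)
HEALTHY_B = PopulationSpec(
    "healthy_b", mean_D=0.05, sd_D=0.01, mean_area_um2=30.0, sd_area_um2=5.0,
    mean_velocity_mps=0.7,
)

PRESETS: dict[str, PopulationSpec] = {
    s.name: s
    for s in (
        RBC, PBMC, BT474, MDA_MB468,
        JURKAT_500_MBAR, JURKAT_1000_MBAR, JURKAT_1500_MBAR, JURKAT_2000_MBAR,
        CLL, HEALTHY_B,
    )
}
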