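"""Feature catalogue: names, families and the fixed 851-column order.

The handcrafted feature vector follows the IBSI family structure:
18 first-order + 14 shape + 24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM +
5 NGTDM = 107 features on the original image, plus the 93 non-shape
features recomputed on each of the 8 sub-bands of a single-level 3-D
wavelet filtration (8 x 93 = 744), for 851 in total.  Shape is computed
once, never per sub-band.  Names follow ``<filter>_<family>_<feature>``.
"""

from __future__ import annotations

FIRSTORDER = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)

SHAPE = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)

GLCM = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "Imc1", "Imc2", "InverseVariance", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)

GLRLM = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage",
    "GrayLevelVariance", "RunVariance", "RunEntropy",
    "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
)

GLSZM = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage",
    "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
    "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
)

GLDM = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

NGTDM = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

TEXTURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "glcm": GLCM, "glrlm": GLRLM, "glszm": GLSZM, "gldm": GLDM,
    "ngtdm": NGTDM,
}

#: sub-band letters in (z, y, x) axis order, low-pass first
WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

NON_SHAPE_FAMILIES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRSTORDER, **TEXTURE_FAMILIES,
}


def catalogue_names() -> list[str]:
    """The 851 feature names in fixed column order."""
    names: list[str] = []
    for fam, feats in NON_SHAPE_FAMILIES.items():
        if fam == "firstorder":
            names += [f"original_firstorder_{f}" for f in feats]
            names += [f"original_shape_{f}" for f in SHAPE]
        else:
            names += [f"original_{fam}_{f}" for f in feats]
    for band in WAVELET_BANDS:
        for fam, feats in NON_SHAPE_FAMILIES.items():
            names += [f"wavelet-{band}_{fam}_{f}" for f in feats]
    return names


CATALOGUE = tuple(catalogue_names())
assert len(CATALOGUE) == 851 and len(set(CATALOGUE)) == 851
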