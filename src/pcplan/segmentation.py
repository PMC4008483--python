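"""Artery segmentation: Otsu body mask and the adaptive j·SD threshold loop.

The TOF angiogram shows flowing blood bright against static tissue.  The
body (tissue + vessels) is first separated from air with Otsu's threshold.
The artery threshold is then set adaptively as

    T_j = mu_O + j * sigma_O

where mu_O and sigma_O are the mean and (population) standard deviation of
the intensities inside the body region O.  Because arterial intensity is
inhomogeneous, j is searched downward from 5 to 3: the first j at which all
four identified arteries span at least 60% of the z scan range is accepted.
If no j qualifies, the lower-bound mask is returned and the downstream
>=3-artery rule decides whether the subject is usable at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from . import artery_id
from .artery_id import ArteryLabeling, ConnectedObject, CrossSection
from .volume_io import BinaryMask3D, Volume3D

__all__ = ["ThresholdSearchResult", "otsu_body_mask", "adaptive_artery_threshold"]


@dataclass
class ThresholdSearchResult:
    """Outcome of the descending-j artery threshold search."""

    j: int
    threshold: float
    mask: BinaryMask3D
    fractions: dict  # artery label -> z-extent fraction (identified arteries only)
    status: str  # "accepted" | "accepted_at_lower_bound"
    labeling: ArteryLabeling
    candidates: list = field(default_factory=list)
    sections: list = field(default_factory=list)


def otsu_body_mask(volume: Volume3D) -> BinaryMask3D:
    """Voxels inside the body (the object region O), by Otsu's threshold.

    Otsu's method picks the threshold minimizing intra-class variance on a
    256-bin histogram of the whole volume; everything above it — tissue and
    vessels — is the body, everything below is air.
    """
    data = volume.data
    if np.min(data) == np.max(data):
        raise ValueError("constant volume: no threshold separates body from air")
    thr = threshold_otsu(data, nbins=256)
    return BinaryMask3D.from_parent(volume, data > thr)


def _z_fractions(labeling: ArteryLabeling, n_z: int) -> dict:
    return {
        lbl: (obj.z_extent) / n_z
        for lbl, (obj, _sec) in labeling.arteries.items()
    }


def adaptive_artery_threshold(
    volume: Volume3D,
    body: BinaryMask3D,
    j_high: int = 5,
    j_low: int = 3,
    length_fraction: float = 0.6,
    n_candidates: int = 8,
) -> ThresholdSearchResult:
    """Search j from *j_high* down to *j_low* for a satisfactory artery mask.

    At each j the volume is thresholded at ``mu_O + j*sigma_O``, candidate
    objects are extracted and labeled (delegating to :mod:`pcplan.artery_id`),
    and each identified artery's z-extent fraction ``(z_max - z_min + 1)/N_z``
    is measured.  The first j at which all four arteries are found with
    fraction >= *length_fraction* is accepted; otherwise the j_low result is
    returned with status ``"accepted_at_lower_bound"``.
    """
    if j_high < j_low or j_low < 1:
        raise ValueError(f"need j_high >= j_low >= 1, got {j_high}, {j_low}")
    if not np.any(body.data):
        raise ValueError("empty body mask")
    body_vals = volume.data[body.data]
    mu = float(np.mean(body_vals))
    sigma = float(np.std(body_vals))  # population SD
    n_z = volume.shape[2]

    result = None
    for j in range(j_high, j_low - 1, -1):
        threshold = mu + j * sigma
        mask = BinaryMask3D.from_parent(volume, volume.data > threshold)
        objects = artery_id.connected_components(mask)
        candidates = artery_id.select_candidates(objects, k=n_candidates)
        sections = artery_id.middle_slice_sections(candidates, volume.shape)
        labeling = artery_id.label_arteries(candidates, sections, volume)
        fractions = _z_fractions(labeling, n_z)
        result = ThresholdSearchResult(
            j=j,
            threshold=threshold,
            mask=mask,
            fractions=fractions,
            status="accepted",
            labeling=labeling,
            candidates=candidates,
            sections=sections,
        )
        if labeling.n_found == 4 and all(f >= length_fraction for f in fractions.values()):
            return result
    result.status = "accepted_at_lower_bound"
    return result
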