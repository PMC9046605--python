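"""Multi-segment foot kinematics.

Joint rotations follow the Joint Coordinate System (JCS) convention for a
five-segment foot model (shank, calcaneus, midfoot, metatarsus, hallux;
joints Sha-Cal, Cal-Mid, Mid-Met, Cal-Met, Met-Hal):

* sagittal-plane rotation about the proximal segment's z axis (medio-lateral),
  dorsiflexion positive;
* transverse-plane rotation about the distal segment's y axis (vertical);
* frontal-plane rotation about the floating axis mutually perpendicular to the
  other two, eversion positive / inversion negative for Sha-Cal.

With the first (body-fixed) axis z, the third (body-fixed) axis y and the
floating axis x, the JCS decomposition of the relative rotation
``R = Rp^T Rd`` is exactly the intrinsic Z-X-Y Euler sequence, which is how it
is computed here (scipy Rotation).

Planar angles (metatarsal inclinations F2G/S2G/V2G, transverse divergences
S2F/S2V, and the medial longitudinal arch angle MLA) are computed from marker
coordinates in the laboratory frame, where the vertical axis is y.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError

#: laboratory vertical (ground-plane normal); x is anterior, z medio-lateral
LAB_VERTICAL = np.array([0.0, 1.0, 0.0])

JOINTS = ("Sha-Cal", "Cal-Mid", "Mid-Met", "Cal-Met", "Met-Hal")
PLANAR_CHANNELS = ("F2G", "S2G", "V2G", "S2F", "S2V", "MLA")
PLANES = ("sagittal", "frontal", "transverse")

#: gimbal guard: flag frontal angles within this many degrees of +-90
GIMBAL_GUARD_DEG = 1.0


@dataclass
class JointAngleSeries:
    """JCS angle triplet for one joint, degrees, one value per time sample."""

    joint: str
    sagittal: np.ndarray
    frontal: np.ndarray
    transverse: np.ndarray
    gimbal: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def plane(self, name: str) -> np.ndarray:
        return {"sagittal": self.sagittal, "frontal": self.frontal,
                "transverse": self.transverse}[name]


def _as_matrices(poses: np.ndarray) -> np.ndarray:
    R = np.asarray(poses, dtype=float)
    if R.shape[-2:] != (3, 3):
        raise GeometryError("poses must be arrays of 3x3 rotation matrices")
    return R


def check_orthonormal(R: np.ndarray, tol: float = 1e-9) -> None:
    """Raise if any matrix is not a proper rotation (R^T R = I, det = +1)."""
    R = _as_matrices(R)
    eye = np.eye(3)
    err = np.abs(np.swapaxes(R, -1, -2) @ R - eye).max()
    det_err = np.abs(np.linalg.det(R) - 1.0).max()
    if err > tol or det_err > tol:
        raise GeometryError(
            f"pose matrices not orthonormal within {tol:g} "
            f"(max |R'R-I| = {err:.2e}, max |det-1| = {det_err:.2e})")


def jcs_compose(sagittal, frontal, transverse) -> np.ndarray:
    """Build relative rotation matrices from JCS angles (degrees).

    Inverse of :func:`jcs_angles`: ``R = Rz(sag) Rx(front) Ry(trans)``
    (intrinsic), so composing then decomposing is the identity on angle
    programs away from the gimbal singularity at frontal = +-90 deg.
    """
    ang = np.stack([np.asarray(sagittal, float),
                    np.asarray(frontal, float),
                    np.asarray(transverse, float)], axis=-1)
    flat = ang.reshape(-1, 3)
    R = Rotation.from_euler("ZXY", flat, degrees=True).as_matrix()
    return R.reshape(*ang.shape[:-1], 3, 3)


def jcs_angles(pose_proximal, pose_distal, joint: str = "") -> JointAngleSeries:
    """Decompose the relative rotation of a joint into JCS angles (degrees).

    Parameters
    ----------
    pose_proximal, pose_distal
        Arrays of shape ``(..., 3, 3)`` of lab-frame segment rotation
        matrices (columns are the segment axes expressed in the lab frame).

    Returns
    -------
    JointAngleSeries
        sagittal (about proximal z), frontal (floating x), transverse
        (about distal y) angles plus a per-sample gimbal warning flag set
        where the frontal angle is within 1 degree of +-90.
    """
    Rp = _as_matrices(pose_proximal)
    Rd = _as_matrices(pose_distal)
    rel = np.swapaxes(Rp, -1, -2) @ Rd
    lead = rel.shape[:-2]
    ang = Rotation.from_matrix(rel.reshape(-1, 3, 3)).as_euler("ZXY", degrees=True)
    ang = ang.reshape(*lead, 3)
    sag = ang[..., 0]
    fro = ang[..., 1]
    tra = ang[..., 2]
    gimbal = np.abs(np.abs(fro) - 90.0) < GIMBAL_GUARD_DEG
    if np.any(gimbal):
        warnings.warn(f"{joint or 'joint'}: frontal angle within "
                      f"{GIMBAL_GUARD_DEG} deg of gimbal singularity", stacklevel=2)
    return JointAngleSeries(joint, sag, fro, tra, np.atleast_1d(gimbal))


def mla_angle(heel_marker, mid_marker, first_met_head_marker) -> np.ndarray:
    """Medial longitudinal arch angle at the arch-apex marker, degrees.

    Angle at the apex (mid) vertex between the limb vectors to the heel and
    to the first metatarsal head; 180 deg is a completely flat arch, so a
    larger angle means a flatter arch. Accepts single points or time series
    of shape ``(..., 3)``; invariant under rigid transforms of all markers.
    """
    a = np.asarray(heel_marker, float) - np.asarray(mid_marker, float)
    b = np.asarray(first_met_head_marker, float) - np.asarray(mid_marker, float)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na == 0.0) or np.any(nb == 0.0):
        raise GeometryError("MLA markers coincide (zero-length limb vector)")
    cosang = np.clip(np.sum(a * b, axis=-1) / (na * nb), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def metatarsal_inclination(base_marker, head_marker,
                           vertical_axis=LAB_VERTICAL) -> np.ndarray:
    """Sagittal inclination of a metatarsal axis to the ground plane, degrees.

    Positive when the head lies below the base (a declining metatarsal).
    """
    v = np.asarray(head_marker, float) - np.asarray(base_marker, float)
    u = np.asarray(vertical_axis, float)
    u = u / np.linalg.norm(u)
    if np.any(np.linalg.norm(v, axis=-1) == 0.0):
        raise GeometryError("zero-length metatarsal axis")
    drop = -np.sum(v * u, axis=-1)            # positive when head is lower
    horiz = v - np.sum(v * u, axis=-1, keepdims=True) * u
    return np.degrees(np.arctan2(drop, np.linalg.norm(horiz, axis=-1)))


def metatarsal_divergence(axis_a, axis_b, vertical_axis=LAB_VERTICAL) -> np.ndarray:
    """Signed transverse-plane angle from axis_a to axis_b, degrees.

    Both axes are projected onto the ground plane; the sign follows the
    right-hand rule about the vertical axis.
    """
    u = np.asarray(vertical_axis, float)
    u = u / np.linalg.norm(u)
    pa = np.asarray(axis_a, float)
    pb = np.asarray(axis_b, float)
    pa = pa - np.sum(pa * u, axis=-1, keepdims=True) * u
    pb = pb - np.sum(pb * u, axis=-1, keepdims=True) * u
    na = np.linalg.norm(pa, axis=-1)
    nb = np.linalg.norm(pb, axis=-1)
    if np.any(na < 1e-12) or np.any(nb < 1e-12):
        raise GeometryError("metatarsal axis has vanishing ground-plane projection")
    cross = np.cross(pa, pb)
    return np.degrees(np.arctan2(np.sum(cross * u, axis=-1),
                                 np.sum(pa * pb, axis=-1)))


# ---------------------------------------------------------------------------
# Trial-level extraction


def joint_angle_channels(segment_poses: dict) -> dict:
    """JCS angles for the five model joints from lab-frame segment poses.

    ``segment_poses`` maps segment name -> (rotations (n,3,3), origins (n,3)).
    Returns ``{joint: JointAngleSeries}``.
    """
    pairs = {"Sha-Cal": ("shank", "calcaneus"),
             "Cal-Mid": ("calcaneus", "midfoot"),
             "Mid-Met": ("midfoot", "metatarsus"),
             "Cal-Met": ("calcaneus", "metatarsus"),
             "Met-Hal": ("metatarsus", "hallux")}
    out = {}
    for joint, (prox, dist) in pairs.items():
        out[joint] = jcs_angles(segment_poses[prox][0], segment_poses[dist][0], joint)
    return out


def planar_channels(markers: dict, vertical_axis=LAB_VERTICAL) -> dict:
    """Planar arch/metatarsal angle time series from marker trajectories.

    Marker names: heel, arch_apex (sustentaculum-tali/navicular proxy),
    met{1,2,5}_base, met{1,2,5}_head, hallux. The arch apex stands in for the
    anatomical MLA landmark; the triad heel-apex-met1_head defines the MLA.
    Divergences are measured from the second metatarsal axis (S2F to the
    first, S2V to the fifth).
    """
    ax = {k: markers[f"met{k}_head"] - markers[f"met{k}_base"] for k in (1, 2, 5)}
    return {
        "F2G": metatarsal_inclination(markers["met1_base"], markers["met1_head"], vertical_axis),
        "S2G": metatarsal_inclination(markers["met2_base"], markers["met2_head"], vertical_axis),
        "V2G": metatarsal_inclination(markers["met5_base"], markers["met5_head"], vertical_axis),
        "S2F": metatarsal_divergence(ax[2], ax[1], vertical_axis),
        "S2V": metatarsal_divergence(ax[2], ax[5], vertical_axis),
        "MLA": mla_angle(markers["heel"], markers["arch_apex"], markers["met1_head"]),
    }
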