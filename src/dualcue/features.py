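"""Constrained maximum-entropy selection of binary image patches.

An early visual stage is modelled as a filter that can store only ``N``
distinct binary patches (limited storage) and transmit at most a total
probability mass ``W`` of matches per unit input (limited bandwidth).
The patches that maximise the transmitted entropy

    H(D) = -sum_{i in D} p_i log2 p_i      s.t.  |D| <= N,  sum p_i <= W

are the *optimal* (salient) features; the patches with the lowest
probability of occurrence are the *non-optimal* (non-salient) control
features.  Probabilities ``p_i`` are estimated from the sliding-window
statistics of binarised images.

Selected patches are rendered as small luminance bitmaps that serve as
attentional cues (default 3x3 cells expanded to 9x9 pixels, black
4 cd/m^2 / white 44 cd/m^2 on a 16 cd/m^2 grey background).
"""

from __future__ import annotations

import csv
import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PatchDistribution",
    "FeatureDictionary",
    "CueBitmap",
    "LuminanceBalance",
    "binarize_image",
    "estimate_patch_distribution",
    "select_optimal_features",
    "select_nonoptimal_features",
    "render_cue",
    "render_control_cue",
    "check_luminance_balance",
    "synthetic_natural_images",
    "write_cue_set",
]

LUM_BLACK_CD_M2 = 4.0
LUM_WHITE_CD_M2 = 44.0
LUM_CONTROL_LOW_CD_M2 = 20.0
LUM_CONTROL_HIGH_CD_M2 = 23.0
LUM_BACKGROUND_CD_M2 = 16.0


class DegenerateImageError(ValueError):
    """Raised when an image cannot be binarised by the requested method."""


@dataclass(frozen=True)
class PatchDistribution:
    """Empirical distribution over all binary patches of a fixed side."""

    patch_side: int
    probs: np.ndarray
    total_count: int

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        n = 2 ** (self.patch_side**2)
        if probs.shape != (n,):
            raise ValueError(f"probs must have length {n}, got {probs.shape}")
        if self.total_count < 1:
            raise ValueError("total_count must be >= 1")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be nonnegative and sum to 1")

    @property
    def alphabet_size(self) -> int:
        return self.probs.size

    def to_json(self, path: str | Path) -> None:
        payload = {
            "patch_side": self.patch_side,
            "total_count": self.total_count,
            "probs": self.probs.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PatchDistribution":
        d = json.loads(Path(path).read_text())
        return cls(d["patch_side"], np.asarray(d["probs"]), d["total_count"])


@dataclass(frozen=True)
class FeatureDictionary:
    """A selected patch set with its constraint parameters.

    ``kind`` is ``"optimal"`` for the constrained-entropy maximiser and
    ``"nonoptimal"`` for the lowest-probability set.  ``warning`` is set
    when the constraints admit no non-empty dictionary.
    """

    patches: tuple
    N: int
    W: float
    achieved_entropy: float
    kind: str
    patch_side: int = 3
    probs: tuple = field(default=())
    warning: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "patches", tuple(int(c) for c in self.patches))
        object.__setattr__(self, "probs", tuple(float(p) for p in self.probs))
        if len(set(self.patches)) != len(self.patches):
            raise ValueError("patches must be unique")
        if len(self.patches) > self.N:
            raise ValueError("dictionary exceeds its size bound N")

    def __len__(self) -> int:
        return len(self.patches)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "patches": list(self.patches),
            "N": self.N,
            "W": self.W,
            "achieved_entropy": self.achieved_entropy,
            "kind": self.kind,
            "patch_side": self.patch_side,
            "probs": list(self.probs),
            "warning": self.warning,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureDictionary":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class CueBitmap:
    """A rendered cue: a small bitmap of luminance values in cd/m^2."""

    pixels: np.ndarray
    side_px: int
    lum_black: float
    lum_white: float
    background: float = LUM_BACKGROUND_CD_M2

    @property
    def mean_luminance(self) -> float:
        return float(np.mean(self.pixels))


@dataclass(frozen=True)
class LuminanceBalance:
    difference_cd_m2: float
    tolerance_cd_m2: float

    @property
    def balanced(self) -> bool:
        return self.difference_cd_m2 <= self.tolerance_cd_m2


def binarize_image(image: np.ndarray, method: str = "median") -> np.ndarray:
    """Binarise a grayscale image to {0, 1}.

    ``median`` thresholds at the image median with ties (value equal to
    the median) mapped to 1.  ``otsu`` requires a bimodal histogram and
    raises :class:`DegenerateImageError` on constant images.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise DegenerateImageError("empty image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if method == "median":
        return (image >= np.median(image)).astype(np.uint8)
    if method == "mean":
        return (image >= np.mean(image)).astype(np.uint8)
    if method == "otsu":
        if np.ptp(image) == 0:
            raise DegenerateImageError("constant image has no Otsu threshold")
        from skimage.filters import threshold_otsu

        return (image >= threshold_otsu(image)).astype(np.uint8)
    raise ValueError(f"unknown binarization method: {method!r}")


def _patch_weights(patch_side: int) -> np.ndarray:
    # Row-major bit order, most-significant bit at the top-left cell.
    n = patch_side**2
    return (2.0 ** np.arange(n - 1, -1, -1)).reshape(patch_side, patch_side)


def estimate_patch_distribution(
    images: list[np.ndarray] | np.ndarray, patch_side: int = 3
) -> PatchDistribution:
    """Count every patch_side x patch_side window (stride 1, no wrap).

    Input images must already be binary ({0, 1}); use
    :func:`binarize_image` first.
    """
    if isinstance(images, np.ndarray) and images.ndim == 2:
        images = [images]
    weights = _patch_weights(patch_side)
    n_codes = 2 ** (patch_side**2)
    counts = np.zeros(n_codes, dtype=np.int64)
    total = 0
    for idx, img in enumerate(images):
        img = np.asarray(img)
        if img.ndim != 2 or min(img.shape) < patch_side:
            raise ValueError(
                f"image {idx} with shape {img.shape} is smaller than the "
                f"{patch_side}x{patch_side} patch"
            )
        if not np.isin(img, (0, 1)).all():
            raise ValueError(f"image {idx} is not binary; binarize first")
        windows = np.lib.stride_tricks.sliding_window_view(
            img.astype(float), (patch_side, patch_side)
        )
        codes = np.tensordot(windows, weights, axes=([2, 3], [0, 1]))
        codes = np.rint(codes).astype(np.int64).ravel()
        counts += np.bincount(codes, minlength=n_codes)
        total += codes.size
    if total == 0:
        raise ValueError("no windows counted")
    return PatchDistribution(patch_side, counts / total, total)


def _entropy_terms(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = -p[pos] * np.log2(p[pos])
    return out


_EXACT_LIMIT = 20
_W_TOL = 1e-12


def _exact_select(p: np.ndarray, N: int, W: float) -> tuple[np.ndarray, float]:
    """Exhaustive subset search over alphabets of <= 20 positive patches.

    Returns indices (into ``p``) of the entropy-maximising feasible set;
    ties broken toward fewer patches, then the lexicographically
    smallest index set.
    """
    n = p.size
    nsub = 1 << n
    psum = np.zeros(nsub)
    hsum = np.zeros(nsub)
    size = np.zeros(nsub, dtype=np.int64)
    ent = _entropy_terms(p)
    members = (np.arange(nsub)[:, None] >> np.arange(n)[None, :]) & 1
    psum = members @ p
    hsum = members @ ent
    size = members.sum(axis=1)
    feasible = (psum <= W + _W_TOL) & (size <= N)
    hs = np.where(feasible, hsum, -np.inf)
    best_h = hs.max()
    ties = np.flatnonzero(hs >= best_h - 1e-12)
    # prefer smaller sets, then smaller bitmask (== smaller sorted codes)
    order = np.lexsort((ties, size[ties]))
    best = ties[order[0]]
    idx = np.flatnonzero(members[best])
    return idx, float(hsum[best])


def _greedy_by_entropy(p: np.ndarray, N: int, W: float) -> list[int]:
    ent = _entropy_terms(p)
    chosen: list[int] = []
    mass = 0.0
    for i in np.argsort(-ent, kind="stable"):
        if len(chosen) >= N:
            break
        if p[i] > 0 and mass + p[i] <= W + _W_TOL:
            chosen.append(int(i))
            mass += p[i]
    return chosen


def _heuristic_select(p: np.ndarray, N: int, W: float) -> tuple[np.ndarray, float]:
    """Rank by |p - W/N| ascending, then local swap improvement.

    The constrained solutions concentrate near p = W/N (equal sharing of
    bandwidth across the N slots), so candidates closest to that mass
    are tried first; a swap pass then repairs local mistakes.  The
    result is never worse than a greedy-by-entropy baseline.
    """
    ent = _entropy_terms(p)
    target = W / N
    order = [int(i) for i in np.argsort(np.abs(p - target), kind="stable") if p[i] > 0]
    chosen: list[int] = []
    mass = 0.0
    for i in order:
        if len(chosen) >= N:
            break
        if mass + p[i] <= W + _W_TOL:
            chosen.append(i)
            mass += p[i]
    improved = True
    passes = 0
    while improved and passes < 20:
        improved = False
        passes += 1
        in_set = set(chosen)
        outside = [i for i in order if i not in in_set]
        # additions
        for u in outside:
            if len(chosen) < N and mass + p[u] <= W + _W_TOL:
                chosen.append(u)
                in_set.add(u)
                mass += p[u]
                improved = True
        outside = [i for i in order if i not in in_set]
        best_gain, best_swap = 1e-12, None
        for s in chosen:
            for u in outside:
                gain = ent[u] - ent[s]
                if gain > best_gain and mass - p[s] + p[u] <= W + _W_TOL:
                    best_gain, best_swap = gain, (s, u)
        if best_swap is not None:
            s, u = best_swap
            chosen[chosen.index(s)] = u
            mass += p[u] - p[s]
            improved = True
    h_heur = float(ent[chosen].sum()) if chosen else 0.0
    base = _greedy_by_entropy(p, N, W)
    h_base = float(ent[base].sum()) if base else 0.0
    if h_base > h_heur:
        return np.asarray(sorted(base), dtype=int), h_base
    return np.asarray(sorted(chosen), dtype=int), h_heur


def select_optimal_features(
    dist: PatchDistribution, N: int = 50, W: float = 0.05, *, force_heuristic: bool = False
) -> FeatureDictionary:
    """Select the entropy-maximising patch set under size and bandwidth bounds.

    Exact (exhaustive) for alphabets of at most 20 positive-probability
    patches; for larger alphabets a documented heuristic is used whose
    achieved entropy is guaranteed to be at least the greedy-by-entropy
    baseline.  Zero-probability patches are never selected.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 < W <= 1:
        raise ValueError("W must be in (0, 1]")
    p = dist.probs
    pos = np.flatnonzero(p > 0)
    if pos.size == 0:
        raise ValueError("all patch probabilities are zero")
    warning = None
    if p[pos].min() > W + _W_TOL:
        warnings.warn("bandwidth W below every positive patch probability; "
                      "dictionary is empty", stacklevel=2)
        return FeatureDictionary((), N, W, 0.0, "optimal", dist.patch_side, (),
                                 warning="infeasible: W below min positive probability")
    if pos.size <= _EXACT_LIMIT and not force_heuristic:
        idx, h = _exact_select(p[pos], N, W)
    else:
        idx, h = _heuristic_select(p[pos], N, W)
    codes = np.sort(pos[idx])
    return FeatureDictionary(
        tuple(codes), N, W, h, "optimal", dist.patch_side,
        tuple(p[codes]), warning=warning,
    )


def select_nonoptimal_features(dist: PatchDistribution, N: int = 50) -> FeatureDictionary:
    """The N positive-probability patches with smallest probability.

    Ties are broken by ascending patch code.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    p = dist.probs
    pos = np.flatnonzero(p > 0)
    if pos.size < N:
        raise ValueError(
            f"only {pos.size} patches with positive probability; need {N}"
        )
    order = np.lexsort((pos, p[pos]))
    codes = np.sort(pos[order[:N]])
    h = float(_entropy_terms(p[codes]).sum())
    return FeatureDictionary(tuple(codes), N, 1.0, h, "nonoptimal",
                             dist.patch_side, tuple(p[codes]))


def patch_bits(patch_code: int, patch_side: int = 3) -> np.ndarray:
    """Decode a patch code to its binary cell matrix (MSB = top-left)."""
    n = patch_side**2
    if not 0 <= patch_code < 2**n:
        raise ValueError(f"patch code {patch_code} out of range for side {patch_side}")
    bits = (patch_code >> np.arange(n - 1, -1, -1)) & 1
    return bits.reshape(patch_side, patch_side).astype(np.uint8)


def render_cue(
    patch_code: int,
    patch_side: int = 3,
    cell_px: int = 3,
    lum_black: float = LUM_BLACK_CD_M2,
    lum_white: float = LUM_WHITE_CD_M2,
) -> CueBitmap:
    """Render a patch as a luminance bitmap, one cell -> cell_px^2 pixels."""
    if cell_px < 1:
        raise ValueError("cell_px must be >= 1")
    bits = patch_bits(patch_code, patch_side)
    cells = np.where(bits == 1, lum_white, lum_black)
    pixels = np.kron(cells, np.ones((cell_px, cell_px)))
    return CueBitmap(pixels, patch_side * cell_px, lum_black, lum_white)


def render_control_cue(level: str, patch_side: int = 3, cell_px: int = 3) -> CueBitmap:
    """Uniform grey control cue: 20 cd/m^2 (low) or 23 cd/m^2 (high)."""
    lums = {"low": LUM_CONTROL_LOW_CD_M2, "high": LUM_CONTROL_HIGH_CD_M2}
    if level not in lums:
        raise ValueError("level must be 'low' or 'high'")
    side = patch_side * cell_px
    lum = lums[level]
    return CueBitmap(np.full((side, side), lum), side, lum, lum)


def check_luminance_balance(
    set_a: FeatureDictionary,
    set_b: FeatureDictionary,
    lum_black: float = LUM_BLACK_CD_M2,
    lum_white: float = LUM_WHITE_CD_M2,
    tolerance_cd_m2: float = 2.0,
) -> LuminanceBalance:
    """Absolute difference of set-mean cue luminances, with a balance flag."""

    def mean_lum(d: FeatureDictionary) -> float:
        if len(d) == 0:
            raise ValueError("cannot balance an empty feature set")
        fracs = [patch_bits(c, d.patch_side).mean() for c in d.patches]
        return float(np.mean([lum_black + f * (lum_white - lum_black) for f in fracs]))

    diff = abs(mean_lum(set_a) - mean_lum(set_b))
    return LuminanceBalance(diff, tolerance_cd_m2)


def synthetic_natural_images(
    n_images: int = 10, size: int = 256, seed: int = 0, slope: float = 2.0
) -> list[np.ndarray]:
    """Grayscale 1/f^alpha noise images standing in for natural scenes.

    Natural images have an approximately 1/f^2 power spectrum; filtered
    Gaussian noise with that spectrum reproduces the second-order
    statistics that drive the patch distribution without requiring any
    photographic corpus.
    """
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.rfftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0
    amp = f ** (-slope / 2.0)
    amp[0, 0] = 0.0
    out = []
    for _ in range(n_images):
        spec = amp * (rng.normal(size=amp.shape) + 1j * rng.normal(size=amp.shape))
        img = np.fft.irfft2(spec, s=(size, size))
        img = (img - img.min()) / max(np.ptp(img), 1e-12) * 255.0
        out.append(img)
    return out


def _write_pgm(path: Path, pixels: np.ndarray, maxval: int = 255) -> None:
    arr = np.rint(pixels).astype(int)
    lines = [f"P2\n{arr.shape[1]} {arr.shape[0]}\n{maxval}\n"]
    lines += [" ".join(str(v) for v in row) + "\n" for row in arr]
    path.write_text("".join(lines))


def write_cue_set(
    dictionary: FeatureDictionary, out_dir: str | Path, cell_px: int = 3
) -> Path:
    """Render every patch of a dictionary to PGM plus a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["patch_code", "kind", "mean_luminance_cd_m2", "file"])
        for code in dictionary.patches:
            bmp = render_cue(code, dictionary.patch_side, cell_px)
            fname = f"cue_{dictionary.kind}_{code:04d}.pgm"
            # store luminance in cd/m^2 directly; maxval covers the white level
            _write_pgm(out / fname, bmp.pixels, maxval=int(np.ceil(bmp.lum_white)))
            wr.writerow([code, dictionary.kind, f"{bmp.mean_luminance:.4f}", fname])
    return manifest


def exhaustive_oracle(p: np.ndarray, N: int, W: float) -> tuple[set, float]:
    """Plain itertools enumeration of every subset; reference for tests."""
    p = np.asarray(p, dtype=float)
    ent = _entropy_terms(p)
    pos = [i for i in range(p.size) if p[i] > 0]
    best_h, best_set = 0.0, set()
    for r in range(1, min(N, len(pos)) + 1):
        for combo in itertools.combinations(pos, r):
            if p[list(combo)].sum() <= W + _W_TOL:
                h = ent[list(combo)].sum()
                if h > best_h + 1e-12:
                    best_h, best_set = h, set(combo)
    return best_set, float(best_h)
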