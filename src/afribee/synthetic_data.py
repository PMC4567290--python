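"""Synthetic populations with the structure the analyses assume.

The generator emulates a two-component hybrid zone: each worker's
mitotype is Bernoulli(p_african), and its *nuclear* class — which drives
body size, hence the discriminant score — matches the mitotype with
probability λ (the linkage parameter).  λ=1 reproduces the early-
introgression regime in which small bees carry African mitochondria;
λ=0 reproduces a fully admixed population in which morphology carries no
information about the mitotype.

Morphometric measurements are drawn from a 4-variate normal per nuclear
class.  Because only discriminant-score means (not raw measurement
means) are reported for real populations, group means are *calibrated*:
:func:`calibrate_morph_means` shifts a plausible base measurement vector
along the discriminant coefficient vector until it scores exactly at a
target, and the shared covariance is scaled so the score's standard
deviation matches a target misclassification rate.  The default base
measurements and covariance are synthetic, honey-bee-plausible
placeholders, not estimates from any real sample.

Marker sequences are built by construction: African cytb amplicons are
motif-free (one band), European ones carry exactly one interior BglII
site (two visible bands); COI barcodes copy the panel reference with the
diagnostic base set to C (African) or T (European); spacers copy the A
exemplar (African) or a random non-A exemplar (European).  Optional
extra substitutions never touch the motif or the diagnostic site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .mito_markers import ReferencePanel, default_panel
from .morphometrics import (
    INDIVIDUAL_COEFFS,
    INDIVIDUAL_CONST,
    individual_score,
)
from .types import (
    Call,
    DomainError,
    MorphMeasurements,
    SiteSummary,
    Source,
    Specimen,
)

_BASES = np.array(list("ACGT"))
_RETRY_CAP = 10_000

#: Plausible worker measurements (FWL, HWL, FL, TL in mm) used only as a
#: calibration base; synthetic, not estimated from any real sample.
DEFAULT_BASE_MEANS = (9.0, 6.0, 2.6, 3.2)

#: Synthetic placeholder covariance (mm^2); rescaled at sampling time so the
#: discriminant-score spread matches the configured misclassification rate.
DEFAULT_BASE_COV = (
    (0.040, 0.010, 0.004, 0.005),
    (0.010, 0.030, 0.003, 0.004),
    (0.004, 0.003, 0.010, 0.003),
    (0.005, 0.004, 0.003, 0.015),
)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the generator.

    Defaults mirror the studied hybrid zone: 65% African mitotype
    frequency, three bees per foraging site, full mitotype–morphology
    linkage, individual-score group means of -0.428 (African) and 0.902
    (European), and a 9.9% expected misclassification rate for the
    individual discriminant (which fixes the within-group score spread).
    """

    p_african: float = 0.65
    n_bees: int = 100
    n_sites: int = 95
    bees_per_site: int = 3
    linkage: float = 1.0  # λ: P(nuclear class == mitotype)
    target_score_african: float = -0.428
    target_score_european: float = 0.902
    misclassification_rate: float = 0.099
    score_sd: Optional[float] = None  # overrides misclassification_rate if set
    base_means: tuple[float, float, float, float] = DEFAULT_BASE_MEANS
    base_cov: tuple[tuple[float, ...], ...] = DEFAULT_BASE_COV
    attach_morph: bool = True
    attach_sequences: bool = True
    n_extra_mutations: int = 0
    cytb_length: int = 485
    min_visible_bp: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_african < 1:
            raise DomainError(f"p_african={self.p_african} outside (0, 1)")
        if not 0 <= self.linkage <= 1:
            raise DomainError(f"linkage={self.linkage} outside [0, 1]")
        cov = np.asarray(self.base_cov, dtype=float)
        if cov.shape != (4, 4) or not np.allclose(cov, cov.T):
            raise DomainError("base_cov must be a symmetric 4x4 matrix")
        if np.linalg.eigvalsh(cov).min() < -1e-9:
            raise DomainError("base_cov must be positive semi-definite")

    @property
    def effective_score_sd(self) -> float:
        """Within-class score SD implied by the misclassification target.

        With class score means separated by d and a midpoint threshold,
        the misclassification rate of either class is Φ(-d/(2σ)), so
        σ = d / (2·Φ⁻¹(1 - rate)).
        """
        if self.score_sd is not None:
            return self.score_sd
        d = abs(self.target_score_european - self.target_score_african)
        z = norm.ppf(1 - self.misclassification_rate)
        if z <= 0 or d == 0:
            raise DomainError(
                "cannot derive a score SD from misclassification rate "
                f"{self.misclassification_rate} at separation {d}"
            )
        return d / (2 * z)


def calibrate_morph_means(
    base_means: Sequence[float],
    target_score: float,
    coefficients: Sequence[float] = INDIVIDUAL_COEFFS,
    constant: float = INDIVIDUAL_CONST,
) -> np.ndarray:
    """Shift measurement means along the coefficient vector to a target score.

    Returns base + ((target - score(base)) / (w·w))·w, the minimal-norm
    shift whose image under the linear discriminant is exactly
    ``target_score``.
    """
    w = np.asarray(coefficients, dtype=float)
    if not np.any(w):
        raise DomainError("coefficient vector must be non-zero")
    base = np.asarray(base_means, dtype=float)
    current = float(w @ base + constant)
    return base + ((target_score - current) / float(w @ w)) * w


def calibrate_morph_cov(
    base_cov: Sequence[Sequence[float]],
    target_score_sd: float,
    coefficients: Sequence[float] = INDIVIDUAL_COEFFS,
) -> np.ndarray:
    """Scale a covariance so the discriminant score has the target SD."""
    w = np.asarray(coefficients, dtype=float)
    cov = np.asarray(base_cov, dtype=float)
    current_var = float(w @ cov @ w)
    if current_var <= 0:
        raise DomainError("base covariance gives zero score variance")
    return cov * (target_score_sd**2 / current_var)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _motif_free_seq(rng: np.random.Generator, n: int, motif: str) -> str:
    for _ in range(_RETRY_CAP):
        s = _rand_seq(rng, n)
        if motif not in s:
            return s
    raise DomainError(f"could not draw a motif-free sequence of length {n}")


def make_marker_sequences(
    mitotype: Call,
    panel: Optional[ReferencePanel] = None,
    n_extra_mutations: int = 0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    cytb_length: int = 485,
    min_visible_bp: int = 50,
) -> dict[str, str]:
    """Build cytb, COI and spacer sequences consistent with a mitotype.

    African: motif-free cytb, C at the COI diagnostic site, spacer copied
    from the A exemplar.  European: cytb with exactly one interior motif
    occurrence (both fragments visible at ``min_visible_bp``), T at the
    diagnostic site, spacer copied from a random non-A exemplar.
    ``n_extra_mutations`` random substitutions are injected per sequence,
    never touching the motif occurrence or the diagnostic site, and never
    creating a new motif occurrence.
    """
    if mitotype not in (Call.AFRICAN, Call.EUROPEAN):
        raise DomainError(f"mitotype must be african or european, got {mitotype}")
    panel = panel if panel is not None else default_panel()
    if rng is None:
        rng = np.random.default_rng(seed)
    motif = panel.restriction_motif

    if mitotype is Call.AFRICAN:
        cytb = _motif_free_seq(rng, cytb_length, motif)
    else:
        # one interior motif occurrence with both fragments visible
        body_len = cytb_length - len(motif)
        if body_len < 2 * min_visible_bp:
            raise DomainError(
                f"cytb_length={cytb_length} too short for two visible "
                f"fragments at min_visible_bp={min_visible_bp}"
            )
        for _ in range(_RETRY_CAP):
            body = _motif_free_seq(rng, body_len, motif)
            # cut (offset 1) at pos+1 gives fragments pos+1 and len-pos-1
            pos = int(rng.integers(min_visible_bp, cytb_length - min_visible_bp - len(motif) + 1))
            cytb = body[:pos] + motif + body[pos:]
            if cytb.count(motif) == 1:
                break
        else:
            raise DomainError("could not place a unique motif occurrence")

    coi = list(panel.coi_reference)
    coi[panel.diagnostic_offset] = "C" if mitotype is Call.AFRICAN else "T"
    coi = "".join(coi)

    if mitotype is Call.AFRICAN:
        spacer_lineage = "A"
    else:
        non_a = sorted(lin for lin in panel.spacer_exemplars if lin != "A")
        spacer_lineage = non_a[int(rng.integers(0, len(non_a)))]
    spacer = panel.spacer_exemplars[spacer_lineage]

    seqs = {"cytb": cytb, "COI": coi, "spacer": spacer}
    if n_extra_mutations:
        seqs = {
            name: _mutate(
                rng,
                seq,
                n_extra_mutations,
                motif=motif,
                protected={panel.diagnostic_offset} if name == "COI" else frozenset(),
            )
            for name, seq in seqs.items()
        }
    return seqs


def _mutate(
    rng: np.random.Generator,
    seq: str,
    n_mut: int,
    motif: str,
    protected: frozenset[int] | set[int] = frozenset(),
) -> str:
    """Apply n_mut random substitutions avoiding protected sites and the motif.

    Positions inside an existing motif occurrence are protected, and a
    substitution that would create a new motif occurrence is redrawn.
    """
    if n_mut >= len(seq):
        raise DomainError(f"{n_mut} mutations exceed sequence length {len(seq)}")
    protected = set(protected)
    start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            break
        protected.update(range(i, i + len(motif)))
        start = i + 1
    n_motifs = seq.count(motif)

    chars = list(seq)
    free = [i for i in range(len(chars)) if i not in protected]
    if n_mut > len(free):
        raise DomainError("not enough mutable positions")
    done = 0
    for _ in range(_RETRY_CAP):
        if done == n_mut:
            break
        i = free[int(rng.integers(0, len(free)))]
        old = chars[i]
        new = str(_BASES[rng.integers(0, 4)])
        if new == old:
            continue
        chars[i] = new
        if "".join(chars).count(motif) != n_motifs:
            chars[i] = old  # would create/destroy a motif occurrence
            continue
        protected.add(i)
        free.remove(i)
        done += 1
    else:
        raise DomainError("mutation retry cap exceeded")
    return "".join(chars)


def sample_population(
    cfg: SimConfig, panel: Optional[ReferencePanel] = None
) -> list[Specimen]:
    """Draw a worker population under the configured hybrid-zone model.

    Per bee: mitotype ~ Bernoulli(p_african); nuclear class equals the
    mitotype with probability λ and is an independent Bernoulli(p_african)
    draw otherwise; measurements ~ MVN(class means, shared covariance),
    with means calibrated to the target scores and covariance scaled to
    the implied score SD; sequences built via :func:`make_marker_sequences`.
    Fully reproducible from ``cfg.seed`` (per-component child streams, so
    e.g. disabling sequences does not change the morphometric draws).
    """
    root = np.random.SeedSequence(cfg.seed)
    mito_rng, nuc_rng, morph_rng, seq_rng = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    if cfg.attach_sequences:
        panel = panel if panel is not None else default_panel()

    n = cfg.n_bees
    mito = mito_rng.random(n) < cfg.p_african
    linked = nuc_rng.random(n) < cfg.linkage
    independent = nuc_rng.random(n) < cfg.p_african
    nuclear = np.where(linked, mito, independent)

    if cfg.attach_morph:
        sd = cfg.effective_score_sd
        cov = calibrate_morph_cov(cfg.base_cov, sd)
        mean_afr = calibrate_morph_means(cfg.base_means, cfg.target_score_african)
        mean_eur = calibrate_morph_means(cfg.base_means, cfg.target_score_european)
        draws = morph_rng.multivariate_normal(
            np.zeros(4), cov, size=n, method="cholesky"
        )
        means = np.where(nuclear[:, None], mean_afr, mean_eur)
        measurements = np.clip(draws + means, 1e-3, None)

    specimens: list[Specimen] = []
    for i in range(n):
        mitotype = Call.AFRICAN if mito[i] else Call.EUROPEAN
        sp = Specimen(
            specimen_id=f"sim{i:05d}",
            site_id=f"site{i // cfg.bees_per_site:04d}",
            source=Source.FORAGING,
            metadata={
                "true_mitotype": mitotype.value,
                "true_nuclear_class": (
                    Call.AFRICAN if nuclear[i] else Call.EUROPEAN
                ).value,
            },
        )
        if cfg.attach_morph:
            fwl, hwl, fl, tl = measurements[i]
            sp.morph = MorphMeasurements(
                forewing_mm=float(fwl),
                hindwing_mm=float(hwl),
                femur_mm=float(fl),
                tibia_mm=float(tl),
            )
        if cfg.attach_sequences:
            sp.sequences = make_marker_sequences(
                mitotype,
                panel,
                n_extra_mutations=cfg.n_extra_mutations,
                rng=seq_rng,
                cytb_length=cfg.cytb_length,
                min_visible_bp=cfg.min_visible_bp,
            )
        specimens.append(sp)
    return specimens


def sample_sites(cfg: SimConfig) -> list[SiteSummary]:
    """Draw per-site African counts i.i.d. Binomial(bees_per_site, p_african)."""
    if cfg.n_sites < 1 or cfg.bees_per_site < 1:
        raise DomainError("n_sites and bees_per_site must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(5)[4])
    counts = rng.binomial(cfg.bees_per_site, cfg.p_african, size=cfg.n_sites)
    return [
        SiteSummary(
            site_id=f"site{i:04d}", n_bees=cfg.bees_per_site, n_african_mito=int(c)
        )
        for i, c in enumerate(counts)
    ]


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Convenience copy of a config with a different seed."""
    return replace(cfg, seed=seed)
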