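"""Published paradigm-association profiles for the default mode network.

Per-mask density z-scores of BrainMap paradigm classes against three
alternative DMN definitions (the Yeo et al. 7-network parcellation, the
Shirer et al. ICA networks, and the Doucet et al. CAREN consensus atlas),
as reported in the meta-analytic literature.  Each list holds the
paradigms that cleared the Bonferroni-style z > 3.3 cutoff for that mask.
These serve as a worked input for the multi-mask consensus rule.
"""

from __future__ import annotations

from .paradigm_analysis import ParadigmProfile

DMN_MASK_PROFILES: dict[str, list[tuple[str, float]]] = {
    "yeo7": [
        ("Theory of Mind", 13.696),
        ("Semantic Monitor/Discrimination", 5.255),
        ("Episodic Recall", 5.227),
        ("Emotion Induction", 4.768),
        ("Self-Reflection", 3.872),
        ("Deception", 3.69),
        ("Passive Listening", 3.327),
    ],
    "shirer": [
        ("Theory of Mind", 7.986),
        ("Episodic Recall", 5.266),
        ("Self-Reflection", 4.395),
        ("Emotion Induction", 4.262),
        ("Acupuncture", 4.043),
        ("Imagined Objects/Scenes", 3.954),
        ("Reward", 3.458),
        ("Deception", 3.614),
    ],
    "caren": [
        ("Theory of Mind", 8.359),
        ("Semantic Monitor/Discrimination", 6.68),
        ("Episodic Recall", 5.414),
        ("Cued Explicit Recognition/Recall", 4.369),
        ("Emotion Induction", 4.303),
        ("Reasoning/Problem Solving", 4.112),
        ("Reward", 3.647),
        ("Reading (Covert)", 3.601),
        ("Imagined Objects/Scenes", 3.537),
        ("Face Monitor/Discrimination", 3.536),
    ],
}


def dmn_mask_profiles(z_threshold: float = 3.3) -> list[ParadigmProfile]:
    """The three published per-mask profiles as :class:`ParadigmProfile`."""
    return [
        ParadigmProfile.from_scores(name, rows, z_threshold=z_threshold)
        for name, rows in DMN_MASK_PROFILES.items()
    ]
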