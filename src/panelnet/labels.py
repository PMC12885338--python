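"""Canonical node, covariate and wave labels for the nine-domain symptom panel.

The nine symptom domains cover depression (DEP), the somatic and subjective
facets of anxiety (SOM, ANX), insomnia-related sleep quantity/quality (SQQ)
and daytime impairment (DIS), passive and active sleepiness (Pas, AcS), and
suicidal ideation and tendency (SuI, SuT).
"""

NODES: list[str] = ["DEP", "SOM", "ANX", "SQQ", "DIS", "Pas", "AcS", "SuI", "SuT"]

COVARIATES: list[str] = ["age", "gender", "education", "duration"]

WAVES: list[str] = ["T0", "T1", "T2"]

N_NODES: int = len(NODES)
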