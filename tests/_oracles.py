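"""Independent brute-force oracles for the epidemiologic measures.

These deliberately re-derive each measure from its definition with plain
loops, so they share no code with the package implementations they check.
"""

from itertools import combinations

import numpy as np


def npr_bruteforce(registry, t):
    num = den = 0
    for _, row in registry.iterrows():
        if t - 365.0 < row["birth_day"] <= t:
            den += 1
            num += bool(row["nonpaternity"])
    return num / den if den else np.nan


def npr_x_bruteforce(registry, t, x):
    num = den = 0
    for _, row in registry.iterrows():
        death = row.get("death_day", np.inf)
        if not (row["birth_day"] <= t < (death if np.isfinite(death) else np.inf)):
            continue
        age = (t - row["birth_day"]) / 365.0
        if x <= age < x + 1:
            den += 1
            num += bool(row["nonpaternity"])
    return num / den if den else np.nan


def epr_bruteforce(episodes, t):
    lo = t - 365.0
    overlapping = [
        row
        for _, row in episodes.iterrows()
        if row["start_day"] <= t and row["end_day"] > lo
    ]
    married_women = {r["woman_id"] for r in overlapping if r["cls"] == "marital"}
    if not married_women:
        return np.nan
    of_married = [r for r in overlapping if r["woman_id"] in married_women]
    extra = sum(r["cls"] == "extramarital" for r in of_married)
    return extra / len(of_married)


def hsr_bruteforce(registry, t, marital_scope=True):
    sibs = {}
    for _, row in registry.iterrows():
        if row["birth_day"] > t:
            continue
        if marital_scope and row["putative_father_id"] < 0:
            continue
        sibs.setdefault(row["mother_id"], []).append(row["bio_father_id"])
    num = den = 0
    for fathers in sibs.values():
        for a, b in combinations(fathers, 2):
            den += 1
            num += a != b
    return num / den if den else np.nan
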