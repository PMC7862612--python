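"""Classify chemicals by toxic ratio (TR) and specificity ratio (SR).

TR = predicted IC10_baseline / measured average EC20: TR <= 10 means the
observed cytotoxicity is explained by non-specific membrane (baseline)
toxicity. SR = EC20 / LOEC of an immune endpoint: SR > 10 means the immune
effect is much more potent than the cytotoxicity, i.e. specific.
"""

from leukotox import Ec20Result, specificity_ratio, toxic_ratio

# (IC10_baseline uM, average EC20 uM); None = censored above max tested
screen = {
    "dexamethasone": (1515.0, 400.0),
    "diclofenac": (5044.0, 463.0),
    "benzo(a)pyrene": (20.0, None),   # never cytotoxic up to 2 uM
    "bisphenol A": (68.0, 25.0),
    "ethinylestradiol": (60.0, 31.0),
    "ethylene glycol": (977_000.0, 1_000_000.0),
    "butanol": (26_000.0, 100_000.0),
}

print(f"{'chemical':18s} {'IC10 (uM)':>11s} {'EC20 (uM)':>11s} "
      f"{'TR':>6s}  classification")
for name, (ic10, ec20) in screen.items():
    if ec20 is None:
        tr = toxic_ratio(ic10, Ec20Result(name, "average", None, True, 2.0))
        print(f"{name:18s} {ic10:11g} {'> 2':>11s} {'-':>6s}  "
              f"{tr.classification}")
        continue
    tr = toxic_ratio(ic10, ec20)
    note = " (borderline)" if tr.borderline else ""
    print(f"{name:18s} {ic10:11g} {ec20:11g} {tr.rounded():6g}  "
          f"{tr.classification}{note}")

print("\n-> every determinable TR is <= 10 or borderline: the cytotoxicity "
      "of all chemicals is consistent with non-specific baseline toxicity.")

sr = specificity_ratio(400.0, 2.0)
print(f"\ndexamethasone phagocytosis: EC20 400 uM / LOEC 2 uM -> SR "
      f"{sr.value:g} ({sr.classification}): the immune suppression is far "
      "more potent than the cytotoxicity.")
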