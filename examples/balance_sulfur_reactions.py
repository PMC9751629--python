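"""Balance the three sulfur disproportionation reactions and test a redox pairing.

Disproportionation splits one intermediate-oxidation-state sulfur compound
into sulfide (reduced) and sulfate (oxidized) at the same time. The balancer
solves element+charge conservation exactly over the rationals.
"""

from disproteo import (
    TETRATHIONATE_ANCHORS,
    balance,
    parse_reaction,
    product_ratio,
    redox_feasibility,
)

for label, text, anchors in [
    ("elemental sulfur", "S0 + H2O -> SO4^2- + HS^- + H^+", None),
    ("thiosulfate", "S2O3^2- + H2O -> SO4^2- + HS^- + H^+", None),
    (
        "tetrathionate",
        "S4O6^2- + H2O -> S2O3^2- + S3O6^2- + SO4^2- + H^+",
        TETRATHIONATE_ANCHORS,  # conservation alone leaves this one underdetermined
    ),
]:
    rxn = balance(parse_reaction(text, anchors))
    print(f"{label}: {rxn.equation()}")
    print(f"  sulfide:sulfate product ratio = {product_ratio(rxn, 'HS^-', 'SO4^2-')}"
          if "HS^-" in text else "")

# Can a couple at +180 mV (thiosulfate -> tetrathionate oxidation) donate
# electrons to menaquinone MK-8 at -70 mV? delta_E < 0 means no: the flow
# would be uphill, so that oxidation route is thermodynamically blocked.
de, favorable, dg = redox_feasibility(donor=180.0, acceptor=-70.0, n_electrons=2)
print(f"thiosulfate/tetrathionate -> MK-8: delta_E = {de:.0f} mV, "
      f"delta_G = {dg:+.1f} kJ/mol, favorable: {favorable}")
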