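"""Design the capsaicin dilution series and the PROP solution.

Ten 1:2 dilutions from a 2.243 ug/mL ethanol stock give the swab ladder used
for threshold testing (swab 1 = most dilute); the PROP recipe converts a
50 mM target to its mass concentration.
"""

from haplobiva import build_series, molar_to_mass_conc

series = build_series(stock=2.243, factor=2.0, n=10)
print("swab  conc (ug/mL)")
for k in range(1, 11):
    print(f"{k:>4}  {series.swab(k):.4f}")
print()
print(f"PROP 50 mM at 170.23 g/mol = {molar_to_mass_conc(50, 170.23):.2f} mg/mL")
print()
print("Each swab doubles the dose; a subject's threshold phenotype is the")
print("first swab index at which they report a sensation.")
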