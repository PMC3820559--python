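"""Triage one patient from raw assay observations.

A tumor with loss of MLH1 and PMS2 staining and an unstable microsatellite
panel looks MMR-deficient; whether the patient is referred for germline
testing hinges on MLH1-promoter methylation, which marks the common
somatic (sporadic) route to MLH1 silencing.
"""

from lynchtriage import (
    IhcPanel,
    MethylationMeasurement,
    MsiMarkerPanel,
    call_ihc_pattern,
    call_methylation,
    call_msi,
    triage_patient,
)

msi = call_msi(MsiMarkerPanel("unstable", "unstable", "stable", "stable",
                              "unstable"))
pattern = call_ihc_pattern(IhcPanel("lost", "retained", "retained", "lost"))
print(f"MSI call: {msi.status.value} "
      f"({msi.n_unstable}/{msi.n_informative} markers unstable)")
print(f"IHC loss pattern: {sorted(pattern.lost)}")

# tumor methylation ratio is the mean of the two promoter probes; 15% cutoff
tumor = MethylationMeasurement(probe_mlh1_3=0.04, probe_mlh1_4=0.06)
meth = call_methylation(tumor)
print(f"Tumor MLH1 promoter: {meth.value}")

decision = triage_patient(pattern, msi, meth_tumor=meth, patient_id="demo-1")
print(f"Label: {decision.label.value}")
print(f"Gene-testing plan: {list(decision.gene_plan)}")
print(f"Rules fired: {list(decision.rationale)}")
# An unmethylated MLH1-loss tumor cannot be explained somatically, so the
# patient is suspected of Lynch syndrome and MLH1 is sequenced first; the
# PMS2 co-loss needs no separate test (PMS2 is destabilised by MLH1 loss).
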