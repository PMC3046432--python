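# Packaged extinction tables

One two-column tab-delimited file per chromophore, `wavelength_nm` and
`epsilon` in cm⁻¹·μM⁻¹ (the decadic ln(10) factor is folded in, so
μa(λ) [cm⁻¹] = ε(λ) · C [μM]).

* `hbo2_extinction_synthetic.tsv` — oxyhemoglobin
* `dhb_extinction_synthetic.tsv` — deoxyhemoglobin
* `bcar_extinction_synthetic.tsv` — β-carotene
* `lymphazurin_extinction_synthetic.tsv` — Lymphazurin (isosulfan blue)

**Provenance.** These tables are *synthetic*: monotone-cubic interpolants
through landmark anchors at the standard visible-range spectral features of
each compound (oxyhemoglobin β/α Q-bands at 542/577 nm, deoxyhemoglobin band
at 556 nm, Soret tails below 460 nm, the broad β-carotene band peaking near
450–480 nm, the rising flank of the isosulfan-blue ~640 nm band), with
magnitudes of the correct order for the real compounds. They are not
digitizations of a measured data set. They are regenerated by
`scripts/make_extinction_tables.py`.

All simulations and inversions in this package are self-consistent against
whatever basis is loaded, so parameter-recovery results do not depend on the
fidelity of these curves to any particular published compilation. Users
fitting real instrument data should substitute their own calibrated tables
(same two-column format) via `ExtinctionBasis.from_files`.
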