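sample_id	morphological_id	barcode_id
KFJ-019	Tetramorium caespitum	Tetramorium caespitum
KFJ-020	Nylanderia cf. flavipes	Nylanderia sp.
KFJ-021	Tapinoma sessile	Tapinoma sessile
KFQ-015	Tetramorium caespitum	Tetramorium caespitum
KFQ-017	Monomorium cf. viride	Monomorium sp.
KFQ-018	Monomorium cf. viride	Monomorium sp.
KFQ-019	Tapinoma sessile	Tapinoma sessile
KHN-003	Tetramorium caespitum	Tetramorium caespitum
KHN-004_1	Tapinoma sessile	Tapinoma sessile
KHN-004_2	Nylanderia cf. parvula	Nylanderia cf. parvula
KHN-006_1	Nylanderia cf. parvula	Nylanderia cf. parvula
KHN-006_2	Tetramorium caespitum	Tetramorium caespitum
KHN-007	Tetramorium caespitum	Tetramorium caespitum
KHN-008	Tetramorium caespitum	Tetramorium sp.
KHN-009	Aphaenogaster sp.	Aphaenogaster rudis
KHN-010	Monomorium cf. viride	Monomorium sp.
KHN-011	Monomorium cf. viride	Monomorium sp.
KHN-012	Nylanderia cf. flavipes	Nylanderia sp.
KHN-013	Monomorium cf. viride	Monomorium sp.
KHN-014	Monomorium cf. viride	Monomorium sp.
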