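sample_id	closest_taxon	taxonomic_level	gene	accession
GQB-003	Ephydridae	family	COI	KU682771
GQB-004	Carabidae	family	COI	KU682774
GQB-007	Gnaphosa sp.	genus	COI	KU682773
GQB-064	Bombyliidae	family	COI	KU682772
GQB-070	Leptothecata	order	COI	KU682775
KDK-019	Spartina sp.	genus	rbcL	KT956910
KDK-021	Ulvellaceae	family	rbcL	KT959344
KDW-016	Mya arenaria	species	COI	KT960977
KHN-010	Monomorium sp.	genus	COI	KX711882
KHN-011	Monomorium sp.	genus	COI	KX711883
KHN-012	Nylanderia sp.	genus	COI	KX711884
KHN-013	Monomorium sp.	genus	COI	KX711885
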