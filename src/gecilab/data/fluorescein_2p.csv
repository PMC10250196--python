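# Fluorescein two-photon action cross-section reference, water pH ~11.
# Approximate digitization of Xu & Webb, J. Opt. Soc. Am. B 13, 481 (1996).
# wavelength_nm,delta_GM
750,21
760,28
770,34
780,37
790,36
800,36
810,37
820,34
830,26
840,19
850,16
860,15
870,16
880,19
890,23
900,16
910,12
920,13
930,12
940,9
950,7
960,6
970,5
980,4
990,3
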