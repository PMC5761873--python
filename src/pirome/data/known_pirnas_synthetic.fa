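>piR-52207 synthetic stand-in matching the documented descriptors (30 nt, GC 56.67%, 1U/10A)
TGGCAGTCGAGGCTCAGCCATGACATTCGA
>piR-33733 synthetic stand-in (30 nt, 1U)
TACGGTAGCCATGGATCGTTACGGCAGATT
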