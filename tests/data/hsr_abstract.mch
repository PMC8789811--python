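machine M0 sees C0
variables hsf hsf2 hsf3 hse hsf3_hse hsp hsp_hsf prot mfp hsp_mfp
invariants
  @inv1 hsf : NAT
  @inv2 hsf2 : NAT
  @inv3 hsf3 : NAT
  @inv4 hse : NAT
  @inv5 hsf3_hse : NAT
  @inv6 hsp : NAT
  @inv7 hsp_hsf : NAT
  @inv8 prot : NAT
  @inv9 mfp : NAT
  @inv10 hsp_mfp : NAT
  @inv11 hsf + 2 * hsf2 + 3 * hsf3 + 3 * hsf3_hse + hsp_hsf = 6
  @inv12 hse + hsf3_hse = 1
  @inv13 hsp_mfp + mfp + prot = 5
events
  event INITIALISATION
    then
      @act1 hsf := 6
      @act2 hsf2 := 0
      @act3 hsf3 := 0
      @act4 hse := 1
      @act5 hsf3_hse := 0
      @act6 hsp := 3
      @act7 hsp_hsf := 0
      @act8 prot := 5
      @act9 mfp := 0
      @act10 hsp_mfp := 0
  end
  event r1_f
    where
      @grd1 hsf >= 2
    then
      @act1 hsf := hsf - 2
      @act2 hsf2 := hsf2 + 1
  end
  event r1_b
    where
      @grd1 hsf2 >= 1
    then
      @act1 hsf := hsf + 2
      @act2 hsf2 := hsf2 - 1
  end
  event r2_f
    where
      @grd1 hsf >= 1
      @grd2 hsf2 >= 1
    then
      @act1 hsf := hsf - 1
      @act2 hsf2 := hsf2 - 1
      @act3 hsf3 := hsf3 + 1
  end
  event r2_b
    where
      @grd1 hsf3 >= 1
    then
      @act1 hsf := hsf + 1
      @act2 hsf2 := hsf2 + 1
      @act3 hsf3 := hsf3 - 1
  end
  event r3_f
    where
      @grd1 hse >= 1
      @grd2 hsf3 >= 1
    then
      @act1 hse := hse - 1
      @act2 hsf3 := hsf3 - 1
      @act3 hsf3_hse := hsf3_hse + 1
  end
  event r3_b
    where
      @grd1 hsf3_hse >= 1
    then
      @act1 hse := hse + 1
      @act2 hsf3 := hsf3 + 1
      @act3 hsf3_hse := hsf3_hse - 1
  end
  event r4
    where
      @grd1 hsf3_hse >= 1
    then
      @act1 hsp := hsp + 1
  end
  event r5_f
    where
      @grd1 hsf >= 1
      @grd2 hsp >= 1
    then
      @act1 hsf := hsf - 1
      @act2 hsp := hsp - 1
      @act3 hsp_hsf := hsp_hsf + 1
  end
  event r5_b
    where
      @grd1 hsp_hsf >= 1
    then
      @act1 hsf := hsf + 1
      @act2 hsp := hsp + 1
      @act3 hsp_hsf := hsp_hsf - 1
  end
  event r6
    where
      @grd1 hsf2 >= 1
      @grd2 hsp >= 1
    then
      @act1 hsf := hsf + 1
      @act2 hsf2 := hsf2 - 1
      @act3 hsp := hsp - 1
      @act4 hsp_hsf := hsp_hsf + 1
  end
  event r7
    where
      @grd1 hsf3 >= 1
      @grd2 hsp >= 1
    then
      @act1 hsf := hsf + 2
      @act2 hsf3 := hsf3 - 1
      @act3 hsp := hsp - 1
      @act4 hsp_hsf := hsp_hsf + 1
  end
  event r8
    where
      @grd1 hsf3_hse >= 1
      @grd2 hsp >= 1
    then
      @act1 hse := hse + 1
      @act2 hsf := hsf + 2
      @act3 hsf3_hse := hsf3_hse - 1
      @act4 hsp := hsp - 1
      @act5 hsp_hsf := hsp_hsf + 1
  end
  event r9
    where
      @grd1 hsp >= 1
    then
      @act1 hsp := hsp - 1
  end
  event r10
    where
      @grd1 prot >= 1
    then
      @act1 mfp := mfp + 1
      @act2 prot := prot - 1
  end
  event r11_f
    where
      @grd1 hsp >= 1
      @grd2 mfp >= 1
    then
      @act1 hsp := hsp - 1
      @act2 hsp_mfp := hsp_mfp + 1
      @act3 mfp := mfp - 1
  end
  event r11_b
    where
      @grd1 hsp_mfp >= 1
    then
      @act1 hsp := hsp + 1
      @act2 hsp_mfp := hsp_mfp - 1
      @act3 mfp := mfp + 1
  end
  event r12
    where
      @grd1 hsp_mfp >= 1
    then
      @act1 hsp := hsp + 1
      @act2 hsp_mfp := hsp_mfp - 1
      @act3 prot := prot + 1
  end
end
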