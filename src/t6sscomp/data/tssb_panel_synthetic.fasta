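>tssb_i1_1 subtype=i1 synthetic=true
CSQIKVCQFCMYRSPSMPTLMIEWSPKHMKLFCNVCVTGPESRICYKVQSSEIFLAMERQ
WRIYKHWICLSELDQLYFNQWKETPRCHSTKTTIVGFQPDTETASSSQLRGSNLQNADIH
KQQLVCCSNPNNCNSHPAHKYFGKYVAFTCVGWGKQDNMSYQKKKTHE
>tssb_i1_2 subtype=i1 synthetic=true
CSQKKVCQFCMYRSRSMDCLMIEWSPKTMKLFCNVCVTGPESRIKYKVQSSEILRAMERD
WRIYKHWICLSELDQWHFNQWCETPRCHSTKTTIVGFQPDTETASSSQLRGSNLMFADFD
KQQLVNCSHPNNCNSHPAHKYFGKYVAFLCVGWGRQDNMSYQKKKTHE
>tssb_i2_1 subtype=i2 synthetic=true
TNMELVAALRQKHPDNCPPCSKSAELEHQDQWENSEGWYNKHPNGSEYKLGSCYGLQLKW
ENMLTGYHMMTKGAITAVMDHNHDQQDGFQRRWSHDPWYFFADNMIHTLTYHFYDGPMWG
YWEEMAGKYQEVCRTVFVDMLHASHQKIVCRRIGAWWFADCTVQDEIN
>tssb_i2_2 subtype=i2 synthetic=true
TNMEYVASLRQKHPHNCPPCSKSAELEHQDQDMNSEGWYNKHPNGAEYKLLSCCGLQLKW
ENMLTGWHMMTKGAITAVMDHNHDQQDGFQRRGSHDPWYFFADNMIHTLTYHFYPGPMDG
YWEMMAGKYYELCRTVFVQMYHASHQKIVCRRIGAWWFADCTVEREIN
>tssb_i3_1 subtype=i3 synthetic=true
LANNDPTDRDRKAYENEWRTKLPSTAMDGTGSLFHMSPQVSPGKDIWKDQYVGLMWGFYR
TYYDVCLLVDETHHWDSWNEEGNEHDMARCEETCKNMQWITHYMRVSVMALEVFFFPNWK
GAAIWMVDCTDCKWQCTTTWFYHTNSPPPSRDTMHMYVTLSIQPFGCL
>tssb_i3_2 subtype=i3 synthetic=true
LANNDPTDRDRKPYENEWRTKLPSTAQDGTGSDFHMSPWVSPGKDIWKDQYVGLMFGFYR
TTYDVCLNIDETHHWDWWNEEGNELDMWRCRETCKNMQTITHYMRCSVMALEVFFFPNWK
GAAIWMVYCTDPKWPCTTTWFYHTNSPPPSRDTMHMYVTLSIQPFGCD
>tssb_i4a_1 subtype=i4a synthetic=true
MWRDYYETTNKSYSWWCGRNCCMPDEDNANLLQMRSWSMFFNDWTDSDKCLQRKWSFQRH
RVTSPGSIMHHEYDCWNKRIDRENWWISPLDIQYARTYQDGVVPDDLNAQMACLRTKGYL
HKAHMWRSMDIDQVQGSTADQYTQDQPCQVVAFFLDVSLAAWGQWAAA
>tssb_i4a_2 subtype=i4a synthetic=true
MWRDYYETKNKSYSMWCGRNCCMPEADNANLLQMRSWSMLFNDWTDSDRCLQRKWSFQRH
RVTSPGSIMHHEYDVWNKRIFRENWWASPLDIQYARTYKDGVRPDDLNAQMACLRTKGYC
HKAHMWRSMDIYAVQGPTADCYAQDQPCQVVAFFLDVSTEAWGQWAAA
>tssb_i4b_1 subtype=i4b synthetic=true
LRKEICSEIYNLMSGPVNKDFWMHKNKKGPKWEDLMQKWLDDYDWGCHPKSPKPYKEKTF
WNPHWAGKCLDFCNIHNRMPNQPHASHMEKMPMIYMTRNVDWVMRMGSFHMTILATCCVT
ICCGNHLERHCRWAKTRVTIREFPQDMIMYCYKSKHSQDRSIWPHALF
>tssb_i4b_2 subtype=i4b synthetic=true
LRKEICSVIYNLMSGPVNKDFWMHPNMQGTKWEDLMQKWLFDYDWGCHPGSPKPYKEKTF
WNPHWAGKLLDFCNCNNRMPNQPHFSHMEKMPMIYMTRNVDWVMRMPSFHMTILADCCVT
TCCGNHLERHCRWAKTRVKIREFPQDMNMACYKSKHTQDRSIWPHAQF
>tssb_i5_1 subtype=i5 synthetic=true
KQSSKCRIRMVHWTHLMSQVIMKWHNDVIHNLTMMDAIYVPPMEAHHEGAPWQKKHDNNA
KGERMDRYTPVLYSQWMRGYPSLVIDMRTKPNYQKYDYEGNRYRPHADGAMEYLQYVLHY
FKVSPCFNMTGWKTFACIYAIDWQSRGSAVRRITIAWFDPFVKAYMGQ
>tssb_i5_2 subtype=i5 synthetic=true
KQSSPCRIRMVHWIHLMSQVIMKWHNDVIHNLTMMDAIYWPPIEAHHEGAPWQKKLDNNA
KGERMPRYTCVLWSQWMRGYPSLVCDMRLKPNYQKYDYEGTRYRPHANRAMSYLVYRLHY
FKCSPCFNMTGWKFFACIYAIDWQSRQSAVRRITIAWFDPFVKAYMVQ
>tssb_iii_1 subtype=iii synthetic=true
HQDLCCIGNAHLYPNHKKVYYSTMYGHVIFNAVWHMYRFNPQAGVFGHEEHFAGCNGSNS
PKVLWYNQGTQWGSLEENHDKQHYSMWKDAWYRDGVCFNCYLGMSHACVDPISCVQKFYH
LIFKEAGDKVEADMGLAHKKNSLTMGFHNFNLVQHMRHFWLALLVREE
>tssb_iii_2 subtype=iii synthetic=true
HDDICCIFNAHLYPVHKKVYYSMMYGTVIFNHVWHMYRFNPFHGVFGHSEHVAGCNGSNS
PKVLWYNQGTQWGRLEENHDKQHYSMWKDAWYRDGACFDCYLGMSHACVDPISCVQKFYH
LIFKEMGDKVEADMGLAHKKNDLTMPFHNFWLVQHFRHFWLALGVREE
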