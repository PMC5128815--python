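patient_id,piece,discordant_markers,mr_er,mr_her2,seq_er,seq_her2,her2_copy_number,subtype,reexam_er_percent,reexam_her2_ihc,reexam_er,reexam_her2,her2_sish,concordant
RDK1,,ER,+,-,-,-,,Basal,0,0,-,,,Y
RDK2,,ER,-,-,+,-,,LumA,100,0-1+,+,,,Y
RDL1,,ER,+,-,-,-,,Basal,0,0,-,,,Y
RDL2,,ER,+,-,-,-,,Basal,0,0,-,,,Y
RDL3,,ER,+,-,-,-,,Her2,0,2+,-,,,Y
RDL4,,ER,+,+,-,+,,Her2,0,3+,-,,,Y
RDK3,,ER,+,+,-,+,,Her2,20,3+,+,,,N
RDL5,a,ER,+,NA,-,+,,Her2,20,3+,+,,,N
RDL5,b,ER,+,NA,-,+,,Her2,80,2+,+,,,N
RDL6,,ER,+,-,-,-,,Her2,15,0,+,,,N
RDL7,,ER/HER2,+,-,-,+,low amp,LumA,100,1+,+,-,NA,N/N
RDL8,a,HER2,+,+,+,-,low amp,LumB,80,0,+,-,NA,Y
RDL9,,HER2,-,-,-,+,high amp,Her2,0,3+,-,+,NA,Y
RDL10,,HER2,+,+,+,-,low amp,LumB,100,1+,+,+,positive,N
RDL8,b,HER2,+,+,+,-,low amp,LumB,90,1+,+,+,positive,N
RDL11,,HER2,+,+,+,-,low amp,LumB,85,1+-2+,+,+,positive,N
RDL12,,HER2,+,+,+,-,low amp,LumB,100,3+,+,+,NA,N
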